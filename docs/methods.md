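# Methods

This package implements probabilistic transcriptome-wide association
analysis (PTWAS): causal inference from eQTL and GWAS data under the
instrumental-variable (IV) framework, driven by probabilistic eQTL
annotations from Bayesian multi-SNP fine-mapping. The analysis has three
sequential stages — scan (hypothesis testing), exclusion-restriction
diagnosis, and causal-effect estimation — plus a multi-tissue combination
layer and a synthetic-data framework that exercises every stage end to end.

## Model and assumptions

Genetic variants $G$ instrument the exposure (gene expression $x$) for a
complex trait $y$. Causal interpretation requires (i) the instruments are
eQTLs of the target gene, (ii) they are independent of confounders, and
(iii) they affect the trait only through the gene (exclusion restriction,
ER; violations are horizontal pleiotropy). The eQTL and GWAS cohorts are
disjoint (two-sample design), so weak-instrument bias shrinks estimates
toward zero rather than inflating type-I error.

## Fine-mapping (`ptwas.finemap`)

A lightweight Bayesian multi-SNP fine-mapper supplies the probabilistic
annotation triple: posterior model probabilities $P_{M}$ over sparse
multiple-regression models, SNP-level posterior inclusion probabilities
(PIPs, membership sums of $P_M$), and LD-based signal clusters with
signal-level PIPs (SPIPs, member-PIP sums).

For a model $M$ with standardized genotype columns $X_M$ and standardized
expression $y$, effects have the conjugate prior
$b \mid \sigma^2 \sim N(0, v\,\sigma^2 I)$ with reference prior
$p(\sigma^2) \propto 1/\sigma^2$, giving the closed-form log marginal
likelihood used throughout. Defaults: per-SNP prior inclusion $1/p$,
effect-prior variance $v = 0.25$ (standardized scale, diffuse enough for
realistic cis effects while still penalizing weak signals), maximum model
size 5, at most 4096 models retained. Posteriors are normalized over the
retained models plus the null model, which is always retained.

The default search is a forward beam (width 8) over a conditionally
refreshed candidate pool: each level gives the best base a full-width
conditional scan (so masked signals can surface, and the pool is topped up
with the best conditional candidates), and expands the remaining beam
members within the pool. A one-step deletion/swap refinement around the
best model spreads posterior mass across LD partners of each selected SNP,
which is what makes the PIPs of tightly linked SNPs share a signal's mass.
Ties break by SNP index; the procedure is fully deterministic. Exhaustive
enumeration of all subsets up to the size cap is available for small loci
and serves as the oracle in tests (greedy PIPs agree within 0.02 on
ten-SNP loci).

Signal clusters are built greedily: the highest-PIP unassigned SNP seeds a
cluster and any SNP with $r^2 \ge 0.25$ to the seed joins it; SNPs with
PIP < 0.01 are ignored. Because a cluster represents *one* signal, members
must be exchangeable explanations of it: two distinct causal signals in
LD co-occur in high-posterior models, while alternative tags of the same
signal do not, so a SNP is additionally required to have low posterior
co-inclusion with the seed (below 10% of the smaller PIP). Without this
exchangeability screen, signals in moderate LD merge into clusters whose
SPIP approaches 2 — an expected signal count, not a probability — and
whose member-averaged Wald ratios mix two different effects. Clusters are
disjoint, and each SPIP is exactly the sum of member PIPs. All thresholds
are configurable; the defaults reproduce the qualitative behavior of
standard fine-mapping signal clusters, which is all the downstream
statistics rely on.

## Composite IV and scan (`ptwas.composite_iv`)

Each retained model is fit jointly by OLS on the eQTL cohort (centered,
unstandardized dosages, so weights stay in expression-per-allele units),
and per-SNP weights are posterior-averaged across models:
$w_j = \sum_i P_{M_i}\, \hat\beta_{M_i, j}$. The composite IV
$\hat x = \sum_j w_j G_j$ is algebraically identical to the ensemble
prediction $\sum_i P_{M_i} \hat x_{M_i}$ (asserted to 1e-10 in tests).
Singular within-model designs fall back to a tiny ridge with a warning.

With individual-level trait data the scan is the simple regression of $y$
on $\hat x$. With GWAS summary statistics the equivalent burden statistic
is
$z = \sum_j w_j s_j z_j \big/ \sqrt{\omega^\top R\, \omega}$,
$\omega_j = w_j s_j$, where $s_j$ are reference-panel dosage SDs and $R$
is the LD matrix, shrunk as $(1-\lambda) R + \lambda I$ with
$\lambda = 0.05$ to guard against reference-panel mismatch. Weight
sparsity is summarized by the Gini coefficient of $|w|$.

## Estimation (`ptwas.estimation`)

SNP-level: Wald/2SLS ratio $\hat\beta_{xy} = \hat\beta_{gwas} /
\hat\beta_{eqtl}$ from single-SNP summary statistics, with the two-term
delta-method variance
$\sigma^2_{xy} = se_g^2/\beta_e^2 + \beta_g^2 se_e^2/\beta_e^4$.
Instruments with $|\beta_e / se_e| < 10^{-6}$ are refused.

Cluster-level: member probabilities are renormalized to conditional causal
probabilities $\tilde p_i = p_i / q$; the point estimate is
$\sum_i \tilde p_i \hat\beta_{xy,i}$ (law of total expectation) and the
variance $\sum_i \tilde p_i (\sigma^2_{xy,i} + \hat\beta_{xy,i}^2) -
\hat\beta_{xy}^2$ (law of total variance), so disagreement among LD
partners inflates the variance instead of being ignored.

Gene-level: fixed-effect inverse-variance-weighted meta-analysis over
clusters with SPIP at or above the eligibility threshold (default 0.50;
weaker signals are weak instruments and excluded). A single eligible
cluster is estimable with $Q = I^2 = 0$ by convention.

## Exclusion-restriction diagnosis (`ptwas.heterogeneity`)

Across $T \ge 2$ eligible clusters, Cochran's
$Q = \sum_k (\hat\beta_k - \hat{\bar\beta})^2 / \hat\sigma_k^2$ and
$I^2 = \max(0, (Q - T + 1)/Q)$ quantify inconsistency; $I^2 \to 1$
indicates severe ER violation. Deliberately, no hypothesis test is
attached to $Q$ (the interesting null would have to assert heterogeneity);
$I^2$ is a quantitative metric, with a configurable downstream exclusion
threshold defaulting to 0.5. The same statistic across tissues measures
tissue heterogeneity of gene-to-trait effects.

## Multi-tissue combination (`ptwas.multitissue`)

Per-tissue scan p-values are combined with the aggregated Cauchy
association test (uniform weights; valid under dependence), with tail
approximations below 1e-15 to avoid overflow. FDR across genes uses
Storey q-values: $\hat\pi_0$ from the $\lambda$-grid 0.05..0.95 with a
cubic-polynomial smoother evaluated at $\lambda = 0.95$; with fewer than
100 p-values the estimate is unreliable and $\pi_0 = 1$
(Benjamini-Hochberg) is used with a warning.

## Synthetic data (`ptwas.simulate`)

The generator emulates a realistic cis-eQTL + GWAS study:

* **Genotypes.** 1500 cis-SNPs per gene; haplotypes follow a first-order
  Markov copying chain on a latent uniform variate, with the per-site copy
  probability calibrated so adjacent-SNP allele correlation equals
  `ld_decay` (default 0.85) wherever the local MAF pair permits; LD decays
  geometrically with distance. MAFs are marginally Uniform(0.05, 0.5) and
  vary smoothly along the locus (a latent AR(0.995) series), because
  strongly heterogeneous adjacent MAFs cap the attainable binary
  correlation below the target. Dosages are haplotype sums in {0, 1, 2}.
* **Expression.** Sparse causal eQTLs drawn Bernoulli(0.002) per SNP
  (3 expected per gene) with N(0, 0.5) effects, plus a polygenic
  background on all SNPs. The polygenic per-SNP variance is a single
  constant across genes, solved in closed form from the scenario
  parameters so that mean heritability is ~50%; per-gene heritability
  varies with the realized causal draws (their number, effects, and
  allele frequencies). Residual noise is N(0, 1).
* **Trait.** $y = u + \eta x + e$, $e \sim N(0,1)$. The estimation
  scenario fixes $\eta = 1$; the power scenario draws
  $\eta \sim N(0, \phi^2)$ with $\phi^2$ assigned in equal proportions
  from {0, 0.2, 0.5, 0.8, 1, 1.2} ($\phi^2 = 0$ genes are true nulls);
  the heterogeneity scenario adds, to every other gene, a direct
  SNP-to-trait effect (default 1.0 per allele, comparable to a mediated
  causal-SNP effect) bypassing expression.
* **Two-sample design.** 706 individuals, disjointly split 400 (eQTL) /
  306 (GWAS). Expression is only used on the eQTL side, the trait only on
  the GWAS side; the eQTL panel doubles as the LD reference, as in a real
  summary-statistic workflow.

Each gene draws from an independent child seed of the scenario seed, so
experiments are reproducible gene by gene and tables are bit-identical
across reruns.

### What the generator does not capture

Real genotypes have block-structured, highly variable LD (many hundreds of
SNPs in near-perfect LD, interspersed with sharp recombination
boundaries) and a MAF spectrum skewed toward rare variants; real
expression involves covariates, batch structure, and measurement models
that are residualized away upstream. Two consequences matter when reading
the simulation tables:

* Synthetic instruments are *cleaner* than real ones: the top eQTL SNP
  tags its causal variant almost perfectly and common MAFs give larger
  per-allele genotype variance. Estimator noise (RMSE) is therefore
  smaller than would be seen with real-panel LD, the scan passes slightly
  more genes, and fewer genes carry the very diffuse clusters that real
  LD produces.
* Signal clusters here are tight (member $r^2$ typically > 0.7), so the
  between-member term of the cluster variance (law of total variance) is
  small and cluster standard errors are close to exact. Across $T$
  homogeneous-instrument clusters with exact errors, $Q$ is approximately
  $\chi^2_{T-1}$ and the *expected* $I^2$ has a floor of about 0.15 at
  $T = 2$ even when the causal model holds perfectly. Mean $I^2$ values
  in that range over tight-cluster simulations therefore indicate
  calibrated (not conservative) errors, not ER violations; with real,
  diverse-tag clusters the total-variance term inflates cluster SEs and
  deflates observed $I^2$. The $I^2$ diagnostic is a one-sided screen for
  *severe* violations, and the injected-pleiotropy simulation shows the
  intended separation (median $I^2$ above 0.5 for contaminated genes,
  near 0 for clean ones).
* Fine-mapped signals that cross the SPIP 0.5 eligibility bar with modest
  evidence have eQTL effects overestimated by selection (winner's curse),
  which attenuates their Wald ratios toward zero in the two-sample
  design. Under these synthetic conditions that depresses the mean IVW
  estimate by roughly 5-10% below the simulated effect at the 0.5
  threshold; the bias shrinks as the eligibility threshold rises, which
  the threshold-grid tables make visible.

## Numerical choices

* All randomness flows from `numpy` `SeedSequence` spawning; identical
  seeds give identical tables.
* Reported p-values are floored at 1e-300; the ACAT tail approximation
  activates below 1e-15.
* Degenerate inputs fail loudly with typed exceptions (`ValidationError`,
  `WeakInstrumentError`, `UndefinedTestError`); "no eligible instrument"
  is a distinct non-error signal (`NotEstimable`).
* Ties in model search break by SNP index; cluster processing orders by
  descending PIP then SNP id, making clustering invariant to input order.
* Strand-ambiguous (A/T, C/G) SNPs are dropped during allele
  harmonization; effect-allele swaps flip the z sign and are logged.

## Problem sizes

The test suite runs the estimation experiment at 500 genes, the power
experiment at 504 genes (84 per grid value), and the null calibration at
300 genes; `scripts/acceptance.py` runs 1000 estimation genes and 504
power genes. These sizes give standard errors comfortably inside the
tolerances asserted while keeping a full run on one CPU in the tens of
minutes.

## Known limitations

* The fine-mapper is a compact conjugate-Bayes implementation, not a
  re-implementation of any specific production fine-mapper; agreement
  with DAP-style tools is qualitative (model posteriors, PIPs, clusters),
  not numerical.
* Summary-statistic estimation needs GWAS betas and standard errors; with
  z-scores only, effects are on the per-z scale and only relative
  comparisons are meaningful.
* VCF ingestion is not implemented; genotypes enter as plain dosage TSVs.
* Cross-gene correlation (co-regulation of neighboring genes) is outside
  the model: each gene is simulated and analyzed independently.
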