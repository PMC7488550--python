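"""Composite instrumental variables and the gene-trait scan test.

The composite IV for a gene is a weighted allele score built by Bayesian
model averaging over the fine-mapping model posterior: each candidate
association model M_i is fit by least squares on the eQTL cohort, and the
per-SNP weight is the posterior-probability-weighted average of its fitted
effects across models,

    w_j = sum_i P(M_i) beta_hat_{M_i, j}        (beta_hat = 0 if j not in M_i)

so the composite value x_hat = sum_j w_j G_j equals the ensemble prediction
sum_i P(M_i) x_hat_{M_i}. The scan either regresses the observed trait on
x_hat (individual-level data) or evaluates the equivalent burden statistic
from GWAS single-SNP z-scores and an LD reference (summary statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import GeneAnnotation
from .exceptions import UndefinedTestError, ValidationError

__all__ = [
    "CompositeIV",
    "ScanResult",
    "build_composite_iv",
    "scan_individual",
    "scan_summary",
    "gini",
]

_P_FLOOR = 1e-300  # reported p-values are floored here to stay in (0, 1]


@dataclass
class CompositeIV:
    """Per-gene SNP weights (expression units per allele) plus reference SDs."""

    gene_id: str
    tissue: str
    snp_ids: list
    weights: np.ndarray
    genotype_sd: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.genotype_sd = np.asarray(self.genotype_sd, dtype=float)
        if len(self.snp_ids) != self.weights.shape[0]:
            raise ValidationError("weights not aligned to snp_ids")
        if self.genotype_sd.shape != self.weights.shape:
            raise ValidationError("genotype_sd not aligned to weights")

    def predict(self, genotypes, snp_ids=None) -> np.ndarray:
        """Composite IV values x_hat for a genotype matrix (n x p dosages)."""
        G = np.asarray(genotypes, dtype=float)
        if snp_ids is not None:
            col = {s: j for j, s in enumerate(snp_ids)}
            try:
                idx = [col[s] for s in self.snp_ids]
            except KeyError as exc:
                raise ValidationError(f"SNP {exc.args[0]} missing from genotypes")
            G = G[:, idx]
        if G.shape[1] != self.weights.shape[0]:
            raise ValidationError("genotype columns not aligned to weights")
        return G @ self.weights


@dataclass
class ScanResult:
    """Gene-level scan statistic: z and its two-sided normal p-value."""

    gene_id: str
    tissue: str
    z: float
    p_value: float


def build_composite_iv(
    annotation: GeneAnnotation,
    genotypes,
    expression,
    snp_ids=None,
) -> CompositeIV:
    """Fit the BMA weights of the composite IV on an eQTL cohort.

    Each retained association model is fit jointly by OLS on centered,
    unstandardized allele dosages (so weights stay in expression-per-allele
    units); weights are averaged across models by posterior probability.
    ``genotype_sd`` records the reference-panel dosage SDs used by the
    summary-statistic scan.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(expression, dtype=float)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(G.shape[1])]
    col = {s: j for j, s in enumerate(snp_ids)}

    support = sorted(
        {s for m in annotation.models for s in m.snp_ids},
        key=lambda s: col.get(s, -1),
    )
    missing = [s for s in support if s not in col]
    if missing:
        raise ValidationError(f"annotation SNP(s) missing from genotypes: {missing}")
    if not support:
        raise ValidationError(
            f"gene {annotation.gene_id}: no SNP appears in any retained model"
        )
    u_idx = [col[s] for s in support]
    pos = {s: i for i, s in enumerate(support)}

    Xu = G[:, u_idx] - G[:, u_idx].mean(axis=0)
    yc = y - y.mean()
    gram = Xu.T @ Xu
    xty = Xu.T @ yc

    w = np.zeros(len(support))
    warned = False
    for m in annotation.models:
        if m.is_null or m.posterior_prob <= 0.0:
            continue
        ix = [pos[s] for s in m.snp_ids]
        A = gram[np.ix_(ix, ix)]
        b = xty[ix]
        try:
            beta = np.linalg.solve(A, b)
            if not np.all(np.isfinite(beta)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            if not warned:
                warnings.warn(
                    f"gene {annotation.gene_id}: singular within-model design; "
                    "using ridge fallback",
                    stacklevel=2,
                )
                warned = True
            ridge = 1e-8 * np.trace(A) / len(ix) + 1e-12
            beta = np.linalg.solve(A + ridge * np.eye(len(ix)), b)
        w[ix] += m.posterior_prob * beta

    sd = G[:, u_idx].std(axis=0)
    return CompositeIV(annotation.gene_id, annotation.tissue, support, w, sd)


def scan_individual(civ: CompositeIV, genotypes, trait, snp_ids=None) -> ScanResult:
    """Scan test with individual-level data: regress the trait on x_hat."""
    xhat = civ.predict(genotypes, snp_ids=snp_ids)
    y = np.asarray(trait, dtype=float)
    if y.shape[0] != xhat.shape[0]:
        raise ValidationError("trait and genotype sample sizes differ")
    n = y.shape[0]
    xc = xhat - xhat.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise UndefinedTestError(
            f"gene {civ.gene_id}: composite IV has zero variance"
        )
    slope = float(xc @ yc) / sxx
    rss = float(yc @ yc) - slope**2 * sxx
    dof = n - 2
    se = np.sqrt(max(rss, 0.0) / max(dof, 1) / sxx)
    if se == 0.0:
        z = np.sign(slope) * np.inf if slope != 0 else 0.0
    else:
        z = slope / se
    p = max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)
    return ScanResult(civ.gene_id, civ.tissue, float(z), float(p))


def scan_summary(
    civ: CompositeIV,
    gwas_z,
    ld,
    ld_regularization: float = 0.05,
) -> ScanResult:
    """Scan test from GWAS summary statistics (burden form).

    z = (sum_j w_j s_j z_j) / sqrt(sum_jk w_j w_k s_j s_k R_jk), with s_j the
    reference-panel genotype SD and R the (regularized) LD matrix aligned to
    ``civ.snp_ids``. The LD matrix is shrunk as (1-lam) R + lam I to guard
    against reference-panel mismatch.
    """
    z_in = np.asarray(gwas_z, dtype=float)
    R = np.asarray(ld, dtype=float)
    m = len(civ.snp_ids)
    if z_in.shape[0] != m or R.shape != (m, m):
        raise ValidationError("gwas_z / ld not aligned to composite IV SNPs")
    lam = ld_regularization
    Rreg = (1.0 - lam) * R + lam * np.eye(m)
    omega = civ.weights * civ.genotype_sd
    num = float(omega @ z_in)
    den2 = float(omega @ Rreg @ omega)
    if den2 <= 0:
        raise UndefinedTestError(
            "non-positive burden variance; the LD reference is inconsistent -- "
            "increase ld_regularization"
        )
    z = num / np.sqrt(den2)
    p = max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)
    return ScanResult(civ.gene_id, civ.tissue, float(z), float(p))


def gini(weights) -> float:
    """Gini coefficient of the absolute weights (mean-difference form).

    0 = perfectly even allocation, (p-1)/p = all mass on a single SNP.
    """
    a = np.abs(np.asarray(weights, dtype=float))
    if a.size == 0 or not np.any(a > 0):
        raise ValidationError("Gini coefficient undefined for all-zero weights")
    n = a.size
    a = np.sort(a)
    ranks = np.arange(1, n + 1)
    return float((2.0 * ranks - n - 1.0) @ a / (n * a.sum()))
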