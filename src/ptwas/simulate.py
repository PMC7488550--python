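"""Synthetic eQTL + GWAS data generation and end-to-end experiments.

The generative model couples a sparse-plus-polygenic expression
architecture to a linear structural equation for the complex trait:

    x_i = mu + sum_j (beta_j gamma_j + alpha_j) g_ij + eps_i,  eps ~ N(0,1)
    y_i = u + eta x_i + e_i,                                   e   ~ N(0,1)

with gamma_j ~ Bernoulli(causal_freq) selecting the sparse causal eQTLs,
beta_j ~ N(0, sparse_effect_var) their effects, and the polygenic alpha_j
scaled per gene so the expression heritability is close to ``target_h2``.
Genotypes are synthetic diploid dosages built from Markov haplotypes whose
adjacent-SNP allele correlation is held at ``ld_decay``, giving geometric
LD decay with distance. The eQTL and GWAS cohorts are disjoint subsamples
(two-sample design): expression is observed only on the eQTL side, the
trait only on the GWAS side.

``run_experiment`` runs the full pipeline (fine-mapping, composite-IV scan
from summary statistics, cluster-level estimation, I2 diagnosis, and the
top-SNP baseline) over many independent genes and tabulates power,
estimation accuracy, or heterogeneity results.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import SignalCluster
from .composite_iv import build_composite_iv, gini, scan_summary
from .estimation import cluster_estimate, ivw_combine, snp_wald
from .exceptions import NotEstimable, ValidationError, WeakInstrumentError
from .finemap import FinemapConfig, finemap
from .heterogeneity import cochran_q, i_squared
from .multitissue import storey_qvalues

__all__ = [
    "SimScenario",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_trait",
    "run_experiment",
    "marginal_stats",
]

#: smoothness of the latent minor-allele-frequency series along the locus;
#: adjacent MAFs must be near-equal for the haplotype copying chain to reach
#: the requested allele correlation.
_MAF_AR = 0.995


@dataclass
class SimScenario:
    """Full parameterization of one simulation study."""

    n_total: int = 706
    n_eqtl: int = 400
    n_gwas: int = 306
    n_genes: int = 1000
    n_snps: int = 1500
    causal_freq: float = 0.002
    sparse_effect_var: float = 0.5
    target_h2: float = 0.5
    eta_var_grid: tuple = (0.0, 0.2, 0.5, 0.8, 1.0, 1.2)
    eta_fixed: float = 1.0
    ld_decay: float = 0.85
    maf_range: tuple = (0.05, 0.5)
    spip_min: float = 0.50
    pleiotropy_effect: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_eqtl + self.n_gwas > self.n_total:
            raise ValidationError("n_eqtl + n_gwas exceeds n_total")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValidationError("ld_decay must lie in [0, 1)")
        for name in ("causal_freq", "sparse_effect_var", "target_h2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")


def simulate_genotypes(scenario: SimScenario, rng=None) -> np.ndarray:
    """Diploid dosage matrix (n_total x n_snps) with geometric LD decay.

    Haplotypes follow a first-order Markov copying chain on a latent uniform
    variate: with a per-site copy probability the latent value (and hence
    the allele, up to the local MAF difference) is inherited from the
    previous site. The copy probability is calibrated so the correlation
    between adjacent haplotype alleles equals ``ld_decay`` wherever the
    local MAFs permit it. MAFs are marginally uniform on ``maf_range`` and
    vary smoothly along the locus.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n_total, scenario.n_snps
    lo, hi = scenario.maf_range

    # smooth MAF series, marginally Uniform(lo, hi)
    from scipy.signal import lfilter

    innov = rng.standard_normal(p) * np.sqrt(1.0 - _MAF_AR**2)
    innov[0] = rng.standard_normal()
    z = lfilter([1.0], [1.0, -_MAF_AR], innov)
    maf = lo + (hi - lo) * stats.norm.cdf(z)

    # per-site copy probability achieving adjacent allele correlation ld_decay
    f_prev, f_next = maf[:-1], maf[1:]
    fmin = np.minimum(f_prev, f_next)
    fmax = np.maximum(f_prev, f_next)
    kappa = np.sqrt(fmin * (1.0 - fmax) / (fmax * (1.0 - fmin)))
    copy_p = np.minimum(1.0, scenario.ld_decay / kappa) if scenario.ld_decay > 0 \
        else np.zeros(p - 1)

    nh = 2 * n
    fresh = rng.random((nh, p))
    keep = rng.random((nh, p)) < np.concatenate([[0.0], copy_p])
    # each latent value is the fresh draw at the most recent non-copy site
    reset_at = np.where(keep, -1, np.arange(p))
    src = np.maximum.accumulate(reset_at, axis=1)
    u = np.take_along_axis(fresh, src, axis=1)
    haps = (u < maf[np.newaxis, :]).astype(np.int8)
    return (haps[0::2] + haps[1::2]).astype(np.int8)


def polygenic_variance(scenario: SimScenario) -> float:
    """Per-SNP polygenic effect variance implied by the heritability target.

    Expected sparse genetic variance is n_snps * causal_freq *
    sparse_effect_var * E[Var(g)] with E[Var(g)] = 2 E[f(1-f)] under the
    uniform MAF law; the polygenic component makes up the difference to
    target_h2/(1-target_h2) (unit residual variance), floored at zero.
    """
    lo, hi = scenario.maf_range
    e_f = (lo + hi) / 2.0
    e_f2 = (lo**2 + lo * hi + hi**2) / 3.0
    mean_var_g = 2.0 * (e_f - e_f2)
    h2 = scenario.target_h2
    if h2 >= 1.0 or mean_var_g <= 0:
        return 0.0
    target_g2 = h2 / (1.0 - h2)
    e_sparse = (scenario.n_snps * scenario.causal_freq
                * scenario.sparse_effect_var * mean_var_g)
    return max(0.0, target_g2 - e_sparse) / (scenario.n_snps * mean_var_g)


def simulate_expression(genotypes, scenario: SimScenario, rng=None):
    """Expression vector plus ground truth for one gene.

    Sparse causal eQTLs are drawn per SNP. The polygenic background variance
    is a single constant across genes, solved from the scenario parameters
    so that the *average* total genetic variance equals
    target_h2 / (1 - target_h2) times the unit residual variance: gene-to-
    gene heritability then varies with the realized causal eQTL draws (their
    number, effects, and allele frequencies), around a mean of ~target_h2.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape

    gamma = rng.random(p) < scenario.causal_freq
    causal_idx = np.flatnonzero(gamma)
    beta = rng.normal(0.0, np.sqrt(scenario.sparse_effect_var), causal_idx.size)
    sparse = G[:, causal_idx] @ beta if causal_idx.size else np.zeros(n)

    sigma_a2 = polygenic_variance(scenario)
    alpha = rng.normal(0.0, np.sqrt(sigma_a2), p) if sigma_a2 > 0 else np.zeros(p)

    genetic = sparse + (G @ alpha if sigma_a2 > 0 else 0.0)
    x = genetic + rng.standard_normal(n)
    var_gen = float(np.var(genetic))
    truth = {
        "causal_idx": causal_idx,
        "beta": beta,
        "alpha_var": sigma_a2,
        "h2": var_gen / (var_gen + 1.0),
    }
    return x, truth


def simulate_trait(expression, eta: float, rng=None, intercept: float = 0.0):
    """Trait from the linear structural equation y = u + eta x + e."""
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(expression, dtype=float)
    return intercept + eta * x + rng.standard_normal(x.shape[0])


def marginal_stats(X, y):
    """Single-variable OLS slope and SE for each column of X (vectorized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = y.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    ok = sxx > 0
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    dof = max(m - 2, 1)
    se = np.where(ok, np.sqrt(rss / dof / np.where(ok, sxx, 1.0)), np.inf)
    se = np.where(se > 0, se, np.inf)
    return beta, se


# ---------------------------------------------------------------------------
# per-gene pipeline
# ---------------------------------------------------------------------------

def _analyze_gene(G, x, y, eqtl_idx, gwas_idx, scenario, config, gene_id):
    """Run fine-mapping, scan, and estimation for one simulated gene.

    Returns (record dict, list of per-cluster dicts).
    """
    Ge, xe = G[eqtl_idx], x[eqtl_idx]
    Gg, yg = G[gwas_idx], y[gwas_idx]
    rec = {
        "gene": gene_id,
        "scan_z": 0.0,
        "scan_p": 1.0,
        "smr_p": 1.0,
        "est_p": 1.0,
        "n_clusters": 0,
        "n_eligible": 0,
        "max_spip": 0.0,
        "ivw_beta": np.nan,
        "ivw_se": np.nan,
        "n_instruments": 0,
        "i2": np.nan,
        "best_beta": np.nan,
        "best_spip": np.nan,
        "smr_beta": np.nan,
        "smr_se": np.nan,
        "gini": np.nan,
    }
    clusters_out = []

    ann = finemap(Ge, xe, config, gene_id=gene_id)

    # top-eQTL-SNP baseline (strongest marginal association in the eQTL data)
    eb, ese = marginal_stats(Ge, xe)
    ez = np.where(np.isfinite(ese), eb / ese, 0.0)
    top = int(np.argmax(np.abs(ez)))
    gb_top, gse_top = marginal_stats(Gg[:, [top]], yg)
    try:
        w_top = snp_wald(gb_top[0], gse_top[0], eb[top], ese[top], f"snp{top}")
        rec["smr_beta"] = w_top.beta_xy
        rec["smr_se"] = float(np.sqrt(w_top.var_xy))
        z_smr = w_top.beta_xy / rec["smr_se"]
        rec["smr_p"] = float(min(1.0, max(2 * stats.norm.sf(abs(z_smr)), 1e-300)))
    except WeakInstrumentError:
        pass

    support = sorted(
        {s for m in ann.models for s in m.snp_ids},
        key=lambda s: int(s[3:]),
    )
    if not support:
        return rec, clusters_out

    civ = build_composite_iv(ann, Ge, xe)
    sup_idx = [int(s[3:]) for s in civ.snp_ids]
    if np.any(civ.weights != 0):
        rec["gini"] = gini(civ.weights)

    # GWAS summary statistics for the needed SNPs only
    member_idx = sorted(
        {int(s[3:]) for c in ann.clusters for s in c.member_snp_ids}
    )
    need = sorted(set(sup_idx) | set(member_idx))
    gb, gse = marginal_stats(Gg[:, need], yg)
    gwas_beta = dict(zip(need, gb))
    gwas_se = dict(zip(need, gse))

    # composite-IV scan from summary statistics + eQTL-panel LD reference
    z_vec = np.array(
        [gwas_beta[j] / gwas_se[j] if np.isfinite(gwas_se[j]) else 0.0
         for j in sup_idx]
    )
    sub = Ge[:, sup_idx].astype(float)
    sd_ok = sub.std(axis=0) > 0
    if sd_ok.any() and np.any(civ.weights[sd_ok] != 0):
        ld = np.atleast_2d(np.corrcoef(sub, rowvar=False))
        ld = np.nan_to_num(ld, nan=0.0)
        np.fill_diagonal(ld, 1.0)
        scan = scan_summary(civ, z_vec, ld)
        rec["scan_z"], rec["scan_p"] = scan.z, scan.p_value

    # cluster-level estimation
    ests = []
    for c in ann.clusters:
        walds = []
        kept_ids, kept_pips = [], []
        for sid, pip in zip(c.member_snp_ids, c.member_pips):
            j = int(sid[3:])
            if not np.isfinite(gwas_se[j]) or not np.isfinite(ese[j]):
                continue
            try:
                walds.append(
                    snp_wald(gwas_beta[j], gwas_se[j], eb[j], ese[j], sid)
                )
            except WeakInstrumentError:
                continue
            kept_ids.append(sid)
            kept_pips.append(pip)
        if not walds:
            continue
        sub_c = SignalCluster(c.cluster_id, kept_ids, float(np.sum(kept_pips)),
                              member_pips=kept_pips)
        # eligibility is judged on the full cluster SPIP
        sub_c.spip = c.spip
        est = cluster_estimate(sub_c, walds)
        ests.append(est)
        clusters_out.append(
            {
                "gene": gene_id,
                "cluster_id": c.cluster_id,
                "spip": c.spip,
                "beta": est.beta,
                "var": est.var,
            }
        )
    rec["n_clusters"] = len(ests)
    if ests:
        rec["max_spip"] = max(e.spip for e in ests)
    eligible = [e for e in ests if e.spip >= scenario.spip_min and e.var > 0]
    rec["n_eligible"] = len(eligible)
    try:
        eff = ivw_combine(ests, spip_min=scenario.spip_min, gene_id=gene_id)
        rec["ivw_beta"], rec["ivw_se"] = eff.beta, eff.se
        rec["n_instruments"] = eff.n_instruments
        rec["i2"] = eff.i2 if eff.n_instruments >= 2 else np.nan
        z_est = eff.beta / eff.se
        rec["est_p"] = float(min(1.0, max(2 * stats.norm.sf(abs(z_est)), 1e-300)))
        best = max(eligible, key=lambda e: e.spip)
        rec["best_beta"], rec["best_spip"] = best.beta, best.spip
    except NotEstimable:
        pass
    return rec, clusters_out


def _ivw_at_threshold(cl: pd.DataFrame, thr: float):
    """Recompute gene-level IVW estimates and I2 at an SPIP threshold.

    ``cl`` holds one gene's cluster table (columns spip, beta, var).
    Returns (ivw_beta, best_beta, i2 or NaN, n_eligible).
    """
    el = cl[(cl["spip"] >= thr) & (cl["var"] > 0)]
    if el.empty:
        return np.nan, np.nan, np.nan, 0
    w = 1.0 / el["var"].to_numpy()
    betas = el["beta"].to_numpy()
    ivw = float((w * betas).sum() / w.sum())
    best = float(el.loc[el["spip"].idxmax(), "beta"])
    if len(el) >= 2:
        q, _ = cochran_q(betas, np.sqrt(el["var"].to_numpy()))
        i2 = i_squared(q, len(el))
    else:
        i2 = np.nan
    return ivw, best, i2, int(len(el))


def run_experiment(scenario: SimScenario, mode: str, progress: bool = False):
    """Simulate ``n_genes`` independent loci and run the full pipeline.

    Modes
    -----
    power
        Gene-to-trait effect eta ~ N(0, phi2) with phi2 assigned round-robin
        from ``eta_var_grid`` (phi2 = 0 genes are true nulls). Reports
        per-method power at the 5% FDR level (Storey q-values), realized
        FDR, and nominal type-I error among null genes.
    estimation
        eta fixed at ``eta_fixed`` for every gene. Reports the scan pass
        rate at p <= 0.05 and, over passing genes, the mean point estimate
        and RMSE of the IVW / single-best-cluster / top-SNP estimators at a
        grid of SPIP thresholds, plus mean I2.
    heterogeneity
        eta fixed at ``eta_fixed``; every other gene receives an injected
        direct (pleiotropic) SNP-to-trait effect bypassing expression.
        Reports the I2 distribution with and without injection.

    Returns a dict with per-gene table ``genes``, per-cluster table
    ``clusters``, and a mode-specific ``summary`` table.
    """
    if mode not in ("power", "estimation", "heterogeneity"):
        raise ValidationError(f"unknown experiment mode {mode!r}")
    master = np.random.default_rng(scenario.seed)
    perm = master.permutation(scenario.n_total)
    eqtl_idx = np.sort(perm[: scenario.n_eqtl])
    gwas_idx = np.sort(perm[scenario.n_eqtl : scenario.n_eqtl + scenario.n_gwas])
    assert not set(eqtl_idx) & set(gwas_idx)

    config = FinemapConfig()
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.n_genes)
    grid = np.asarray(scenario.eta_var_grid, dtype=float)

    gene_rows, cluster_rows = [], []
    for g in range(scenario.n_genes):
        rng = np.random.default_rng(seeds[g])
        G = simulate_genotypes(scenario, rng)
        x, truth = simulate_expression(G, scenario, rng)
        if mode == "power":
            phi2 = float(grid[g % grid.size])
            eta = float(rng.normal(0.0, np.sqrt(phi2))) if phi2 > 0 else 0.0
        else:
            phi2 = np.nan
            eta = float(scenario.eta_fixed)
        y = simulate_trait(x, eta, rng)
        injected = False
        if mode == "heterogeneity" and g % 2 == 1:
            # direct SNP-to-trait path bypassing expression (ER violation)
            pool = truth["causal_idx"]
            j = int(pool[0]) if pool.size else int(rng.integers(G.shape[1]))
            y = y + scenario.pleiotropy_effect * (G[:, j] - G[:, j].mean())
            injected = True
        rec, cls = _analyze_gene(
            G, x, y, eqtl_idx, gwas_idx, scenario, config, f"gene{g}"
        )
        rec.update(
            eta=eta, phi2=phi2, h2=truth["h2"],
            n_causal=int(truth["causal_idx"].size), injected=injected,
        )
        gene_rows.append(rec)
        cluster_rows.extend(cls)
        if progress and (g + 1) % 50 == 0:
            print(f"  {g + 1}/{scenario.n_genes} genes", file=sys.stderr)

    genes = pd.DataFrame(gene_rows)
    clusters = pd.DataFrame(
        cluster_rows, columns=["gene", "cluster_id", "spip", "beta", "var"]
    )

    if mode == "power":
        summary = _summarize_power(genes)
    elif mode == "estimation":
        summary = _summarize_estimation(genes, clusters, scenario)
    else:
        summary = _summarize_heterogeneity(genes)
    return {"genes": genes, "clusters": clusters, "summary": summary}


def _summarize_power(genes: pd.DataFrame) -> pd.DataFrame:
    nonnull = genes["phi2"] > 0
    rows = []
    for method, col in (
        ("ptwas_scan", "scan_p"),
        ("estimation_z", "est_p"),
        ("smr", "smr_p"),
    ):
        p = genes[col].fillna(1.0).to_numpy()
        q = storey_qvalues(p)
        rej = q <= 0.05
        n_rej = int(rej.sum())
        power = float(rej[nonnull].mean()) if nonnull.any() else np.nan
        fdr = float((rej & ~nonnull).sum() / n_rej) if n_rej else 0.0
        type1 = float((p[~nonnull] <= 0.05).mean()) if (~nonnull).any() else np.nan
        rows.append(
            {
                "method": method,
                "power_fdr05": power,
                "realized_fdr": fdr,
                "n_rejected": n_rej,
                "type1_at_p05": type1,
            }
        )
    return pd.DataFrame(rows)


def _summarize_estimation(genes, clusters, scenario) -> pd.DataFrame:
    eta = float(scenario.eta_fixed)
    passing = genes[genes["scan_p"] <= 0.05]
    pass_frac = float(len(passing)) / len(genes)
    by_gene = dict(tuple(clusters.groupby("gene"))) if len(clusters) else {}
    rows = []
    for thr in (0.5, 0.7, 0.9, 0.95):
        ivw_err, best_err, i2s = [], [], []
        multi_err = []
        for g in passing["gene"]:
            cl = by_gene.get(g)
            if cl is None:
                continue
            ivw, best, i2, n_el = _ivw_at_threshold(cl, thr)
            if np.isfinite(ivw):
                ivw_err.append(ivw - eta)
                best_err.append(best - eta)
            if n_el >= 2:
                multi_err.append(ivw - eta)
            if np.isfinite(i2):
                i2s.append(i2)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e)))) if e else np.nan
        rows.append(
            {
                "spip_min": thr,
                "n_genes": len(ivw_err),
                "mean_estimate": float(np.mean(ivw_err) + eta) if ivw_err else np.nan,
                "rmse_ivw": rmse(ivw_err),
                "rmse_best_cluster": rmse(best_err),
                "rmse_multi_instrument": rmse(multi_err),
                "mean_i2": float(np.mean(i2s)) if i2s else np.nan,
                "n_multi": len(multi_err),
            }
        )
    smr_err = (passing["smr_beta"] - eta).dropna()
    out = pd.DataFrame(rows)
    out["rmse_smr"] = float(np.sqrt(np.mean(np.square(smr_err)))) if len(smr_err) else np.nan
    out["pass_fraction"] = pass_frac
    out["n_passing"] = len(passing)
    return out


def _summarize_heterogeneity(genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for injected, grp in genes.groupby("injected"):
        i2 = grp["i2"].dropna()
        rows.append(
            {
                "injected": bool(injected),
                "n_genes_with_i2": int(len(i2)),
                "mean_i2": float(i2.mean()) if len(i2) else np.nan,
                "median_i2": float(i2.median()) if len(i2) else np.nan,
                "frac_i2_gt_0.5": float((i2 > 0.5).mean()) if len(i2) else np.nan,
            }
        )
    return pd.DataFrame(rows)
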