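"""Gene-to-trait causal effect estimation.

Three layers, mirroring the structure of the annotation:

1. SNP level: the Wald / two-stage-least-squares ratio
   beta_xy = beta_gwas / beta_eqtl with a two-term delta-method variance.
2. Signal-cluster level: member SNP ratios are averaged by conditional
   causal probability p_i / q (Bayesian model averaging over which member
   SNP is the causal one); the variance follows from the law of total
   variance and therefore includes the between-member spread.
3. Gene level: cluster estimates from independent eQTL signals are combined
   by fixed-effect inverse-variance-weighted (IVW) meta-analysis. Only
   strong signals (SPIP >= spip_min, default 0.50) are admitted; Cochran's Q
   and I-squared across the admitted clusters diagnose exclusion-restriction
   violations.

The top-eQTL-SNP estimator (as in SMR) is the single-SNP degenerate case of
layer 1 and is kept as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotations import SignalCluster
from .exceptions import NotEstimable, ValidationError, WeakInstrumentError
from .heterogeneity import cochran_q, i_squared

__all__ = [
    "SnpWald",
    "ClusterEstimate",
    "GeneEffect",
    "snp_wald",
    "cluster_estimate",
    "ivw_combine",
    "effect_z_test",
]


@dataclass
class SnpWald:
    """Single-SNP Wald ratio estimate of the gene-to-trait effect."""

    snp_id: str
    beta_xy: float
    var_xy: float


@dataclass
class ClusterEstimate:
    """BMA estimate of the gene-to-trait effect from one eQTL signal cluster."""

    cluster_id: int
    spip: float
    beta: float
    var: float
    member_estimates: list = field(default_factory=list)
    tilde_p: np.ndarray | None = None


@dataclass
class GeneEffect:
    """IVW-combined gene-level causal effect with heterogeneity diagnostics."""

    gene_id: str
    tissue: str
    beta: float
    se: float
    n_instruments: int
    q_stat: float = 0.0
    i2: float = 0.0


def snp_wald(
    beta_gwas: float,
    se_gwas: float,
    beta_eqtl: float,
    se_eqtl: float,
    snp_id: str = "snp",
) -> SnpWald:
    """Wald/2SLS ratio with two-term delta-method variance.

    beta_xy = beta_gwas / beta_eqtl;
    var_xy  = se_gwas^2 / beta_eqtl^2 + beta_gwas^2 se_eqtl^2 / beta_eqtl^4.
    """
    if se_gwas <= 0 or se_eqtl <= 0:
        raise ValidationError("standard errors must be positive")
    if beta_eqtl == 0 or abs(beta_eqtl / se_eqtl) < 1e-6:
        raise WeakInstrumentError(
            f"{snp_id}: eQTL effect indistinguishable from zero"
        )
    b = beta_gwas / beta_eqtl
    v = se_gwas**2 / beta_eqtl**2 + beta_gwas**2 * se_eqtl**2 / beta_eqtl**4
    return SnpWald(snp_id, float(b), float(v))


def cluster_estimate(cluster: SignalCluster, walds) -> ClusterEstimate:
    """Combine member-SNP Wald ratios within one signal cluster.

    Member probabilities are renormalized to conditional causal
    probabilities tilde_p_i = p_i / q; the point estimate is their weighted
    mean (law of total expectation) and the variance is

        sum_i tilde_p_i (var_i + beta_i^2) - beta^2

    by the law of total variance, so LD-driven disagreement between member
    SNPs inflates the variance rather than being ignored.
    """
    if cluster.spip <= 0:
        raise ValidationError(f"cluster {cluster.cluster_id} has zero SPIP")
    if cluster.member_pips is None:
        raise ValidationError(
            f"cluster {cluster.cluster_id} carries no member PIPs"
        )
    wmap = {w.snp_id: w for w in walds}
    missing = [s for s in cluster.member_snp_ids if s not in wmap]
    if missing:
        raise ValidationError(
            f"cluster {cluster.cluster_id}: missing Wald estimate(s) for {missing}"
        )
    pips = np.asarray(cluster.member_pips, dtype=float)
    tilde_p = pips / pips.sum()
    members = [wmap[s] for s in cluster.member_snp_ids]
    betas = np.array([w.beta_xy for w in members])
    vars_ = np.array([w.var_xy for w in members])
    beta = float(tilde_p @ betas)
    var = float(tilde_p @ (vars_ + betas**2) - beta**2)
    var = max(var, 0.0)  # law of total variance up to roundoff
    return ClusterEstimate(
        cluster.cluster_id, cluster.spip, beta, var, members, tilde_p
    )


def ivw_combine(
    estimates,
    spip_min: float = 0.50,
    gene_id: str = "gene",
    tissue: str = "unknown",
) -> GeneEffect:
    """Fixed-effect IVW meta-analysis over eligible signal clusters.

    Clusters with SPIP below ``spip_min`` are weak instruments and excluded.
    With a single eligible instrument, Q = 0 and I2 = 0 by convention
    (heterogeneity is undefined but the gene remains estimable). Raises
    :class:`NotEstimable` when no cluster qualifies.
    """
    eligible = [e for e in estimates if e.spip >= spip_min and e.var > 0]
    if not eligible:
        raise NotEstimable(
            f"gene {gene_id}: no signal cluster with SPIP >= {spip_min}"
        )
    betas = np.array([e.beta for e in eligible])
    ses = np.sqrt(np.array([e.var for e in eligible]))
    wts = 1.0 / ses**2
    beta = float((wts @ betas) / wts.sum())
    se = float(1.0 / np.sqrt(wts.sum()))
    if len(eligible) >= 2:
        q, _ = cochran_q(betas, ses)
        i2 = i_squared(q, len(eligible))
    else:
        q, i2 = 0.0, 0.0
    return GeneEffect(gene_id, tissue, beta, se, len(eligible), float(q), float(i2))


def effect_z_test(effect: GeneEffect) -> float:
    """Two-sided normal p-value for beta/se (estimation-based scan test)."""
    if effect.se <= 0:
        raise ValidationError("standard error must be positive")
    z = effect.beta / effect.se
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 1e-300)))
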