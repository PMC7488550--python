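"""Multi-tissue combination: ACAT global-null test and Storey q-values.

Per-tissue scan p-values for a gene are combined into a test of the global
null (no effect in any tissue) with the aggregated Cauchy association test
(ACAT), which is valid under arbitrary dependence between tissues. FDR over
genes is then controlled with Storey's q-value procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["GlobalScanRecord", "acat", "storey_qvalues", "global_scan"]


@dataclass
class GlobalScanRecord:
    """Cross-tissue summary for one gene."""

    gene_id: str
    per_tissue_p: dict = field(default_factory=dict)
    acat_p: float = 1.0
    q_value: float = 1.0


def acat(pvals, weights=None) -> float:
    """Cauchy combination of p-values.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i; the combined p-value is
    0.5 - arctan(T)/pi. Tiny p-values (< 1e-15) enter through the tail
    approximation tan((0.5 - p) pi) ~ 1/(p pi), and a huge T maps back via
    p ~ 1/(pi T), both to avoid overflow/cancellation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("acat requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 1 + 1e-12):
        raise ValidationError("p-values must lie in (0, 1)")
    p = np.minimum(p, 1.0 - 1e-16)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be nonnegative, aligned, not all zero")
        w = w / w.sum()
    tiny = p < 1e-15
    terms = np.empty_like(p)
    terms[~tiny] = np.tan((0.5 - p[~tiny]) * np.pi)
    terms[tiny] = 1.0 / (p[tiny] * np.pi)
    t = float(w @ terms)
    if t > 1e15:
        return float(1.0 / (np.pi * t))
    return float(min(1.0, max(0.5 - np.arctan(t) / np.pi, 1e-300)))


def storey_qvalues(pvals, lambdas=None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) and smoothed
    with a cubic fit evaluated at the largest lambda, as in the reference
    q-value procedure. With fewer than 100 p-values the estimate is
    unreliable and pi0 = 1 (Benjamini-Hochberg) is used with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvals must be a non-empty 1-d vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        warnings.warn(
            "fewer than 100 p-values: using pi0 = 1 (Benjamini-Hochberg)",
            stacklevel=2,
        )
        pi0 = 1.0
    else:
        pi0_l = np.array(
            [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
        )
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # monotone in p
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def global_scan(scan_results) -> list:
    """Combine per-tissue scan results into gene-level global-null records.

    ``scan_results`` is an iterable of objects with ``gene_id``, ``tissue``
    and ``p_value`` attributes (one per gene-tissue pair). ACAT combines the
    tissues of each gene with uniform weights; Storey q-values are computed
    across genes.
    """
    by_gene: dict = {}
    for r in scan_results:
        by_gene.setdefault(r.gene_id, {})[r.tissue] = r.p_value
    if not by_gene:
        return []
    records = [
        GlobalScanRecord(g, per_tissue_p=ps, acat_p=acat(list(ps.values())))
        for g, ps in by_gene.items()
    ]
    qs = storey_qvalues([r.acat_p for r in records])
    for r, q in zip(records, qs):
        r.q_value = float(q)
    return records
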