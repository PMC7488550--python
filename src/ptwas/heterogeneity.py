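"""Heterogeneity diagnostics for the exclusion-restriction assumption.

Each independent eQTL signal provides its own estimate of the same
gene-to-trait effect; under a valid instrumental-variable model these
estimates agree up to sampling noise. Cochran's Q measures their weighted
dispersion around the fixed-effect mean, and

    I2 = max(0, (Q - T + 1) / Q)

(T = number of independent estimates) rescales it to [0, 1]. I2 near 0
indicates consistency; I2 near 1 flags a severe exclusion-restriction
violation (horizontal pleiotropy). Deliberately no hypothesis test is
attached to Q: I2 is reported as a quantitative metric with a configurable
exclusion threshold (default 0.5) applied downstream. The same statistic
applied across tissues measures tissue heterogeneity of gene-to-trait
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "HeterogeneityResult",
    "cochran_q",
    "i_squared",
    "er_diagnose",
    "cross_tissue_i2",
]

I2_EXCLUDE_DEFAULT = 0.5


@dataclass
class HeterogeneityResult:
    q: float
    t: int
    i2: float


def cochran_q(betas, ses):
    """Cochran's Q and the fixed-effect (IVW) mean over >= 2 estimates."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValidationError("betas and ses must be 1-d and aligned")
    if b.size < 2:
        raise ValidationError("Cochran's Q needs at least two estimates")
    if np.any(s <= 0):
        raise ValidationError("standard errors must be positive")
    w = 1.0 / s**2
    fixed = float((w @ b) / w.sum())
    q = float(w @ (b - fixed) ** 2)
    return q, fixed


def i_squared(q: float, t: int) -> float:
    """I2 = max(0, (Q - T + 1)/Q); defined as 0 when Q = 0."""
    if t < 2:
        raise ValidationError("I2 requires at least two estimates")
    if q < 0:
        raise ValidationError("Q must be nonnegative")
    if q == 0:
        return 0.0
    return float(max(0.0, (q - t + 1) / q))


def er_diagnose(cluster_estimates, spip_min: float = 0.50):
    """I2 across eligible signal clusters of one gene.

    Returns a :class:`HeterogeneityResult`, or None (not applicable) when
    fewer than two clusters reach ``spip_min``.
    """
    eligible = [
        e for e in cluster_estimates if e.spip >= spip_min and e.var > 0
    ]
    if len(eligible) < 2:
        return None
    betas = [e.beta for e in eligible]
    ses = [np.sqrt(e.var) for e in eligible]
    q, _ = cochran_q(betas, ses)
    return HeterogeneityResult(q, len(eligible), i_squared(q, len(eligible)))


def cross_tissue_i2(effects):
    """I2 of one gene's estimated effects across tissues.

    Returns None (not applicable) with fewer than two finite-SE tissues.
    """
    usable = [e for e in effects if np.isfinite(e.se) and e.se > 0]
    if len(usable) < 2:
        return None
    betas = [e.beta for e in usable]
    ses = [e.se for e in usable]
    q, _ = cochran_q(betas, ses)
    return HeterogeneityResult(q, len(usable), i_squared(q, len(usable)))
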