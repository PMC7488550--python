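"""Lightweight Bayesian multi-SNP fine-mapping of cis-eQTLs.

Produces the probabilistic annotation triple consumed downstream: posterior
model probabilities over sparse multiple-regression models, SNP-level PIPs,
and LD-based signal clusters.

Model: for a candidate SNP set M with standardized genotype columns X_M and
centered/scaled expression y,

    y | b, s2 ~ N(X_M b, s2 I),   b | s2 ~ N(0, v s2 I),   p(s2) ~ 1/s2,

which gives the closed-form log marginal likelihood

    log p(y|M) = lgamma(n/2) - (n/2) log(pi)
                 - 1/2 log|I + v X_M' X_M| - (n/2) log S_M,

with S_M = y'y - y'X_M (X_M'X_M + I/v)^{-1} X_M'y. Models carry a
Bernoulli(prior_inclusion) inclusion prior per SNP. The default search is
greedy-forward with one-step deletion/swap refinement; every model evaluated
along the way enters the Bayesian model average. Exhaustive enumeration over
all subsets up to ``max_model_size`` is available for small loci and serves
as the internal oracle for the greedy mode.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .annotations import (
    AssociationModel,
    GeneAnnotation,
    SnpRecord,
    build_clusters,
)
from .exceptions import ValidationError

__all__ = ["FinemapConfig", "model_log_marginal", "finemap"]


@dataclass
class FinemapConfig:
    """Tuning parameters of the fine-mapper.

    ``prior_inclusion`` defaults to 1/p (set at fit time when None).
    ``effect_prior_variance`` is the per-SNP prior effect variance on the
    standardized (unit-variance genotype and expression) scale.
    """

    max_model_size: int = 5
    prior_inclusion: float | None = None
    effect_prior_variance: float = 0.25
    max_models_retained: int = 4096
    search: str = "greedy-forward"
    r2_min: float = 0.25
    pip_floor: float = 0.01

    def __post_init__(self):
        if self.max_model_size < 1:
            raise ValidationError("max_model_size must be >= 1")
        if self.prior_inclusion is not None and not (0 < self.prior_inclusion < 1):
            raise ValidationError("prior_inclusion must lie in (0,1)")
        if self.search not in ("greedy-forward", "exhaustive"):
            raise ValidationError(f"unknown search mode {self.search!r}")


def _standardize(a: np.ndarray, axis: int = 0):
    """Center and scale to unit variance; zero-variance columns flagged."""
    a = np.asarray(a, dtype=float)
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    ok = (sd > 0).ravel()
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (a - mean) / sd_safe, ok


class _Evaluator:
    """Incremental computation of log marginal likelihoods over SNP subsets."""

    def __init__(self, X: np.ndarray, y: np.ndarray, v: float):
        self.X = X
        self.y = y
        self.v = v
        self.n, self.p = X.shape
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.colsq = np.einsum("ij,ij->j", X, X)
        self.const = gammaln(self.n / 2.0) - (self.n / 2.0) * np.log(np.pi)

    def _logml(self, k: int, logdet_a: float, quad: float) -> float:
        s = max(self.yty - quad, 1e-300)
        return float(
            self.const
            - 0.5 * (k * np.log(self.v) + logdet_a)
            - (self.n / 2.0) * np.log(s)
        )

    def base(self, idx):
        """Stats for a fixed model: (logdetA, quad, A^{-1}, A^{-1} X'y)."""
        idx = list(idx)
        k = len(idx)
        if k == 0:
            return 0.0, 0.0, np.zeros((0, 0)), np.zeros(0)
        Xm = self.X[:, idx]
        A = Xm.T @ Xm + np.eye(k) / self.v
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            raise ValidationError("non-positive-definite model Gram matrix")
        Ainv = np.linalg.inv(A)
        c = Ainv @ self.Xty[idx]
        quad = float(self.Xty[idx] @ c)
        return logdet, quad, Ainv, c

    def logml(self, idx) -> float:
        idx = list(idx)
        logdet, quad, _, _ = self.base(idx)
        return self._logml(len(idx), logdet, quad)

    def eval_additions(self, idx, cols=None):
        """Log marginal of ``idx + [j]`` for candidate SNPs j, vectorized.

        Returns a length-p vector; entries outside ``cols`` (when given),
        SNPs already in the model, and degenerate candidates are -inf.
        """
        idx = list(idx)
        k = len(idx)
        logdet0, quad0, Ainv, c = self.base(idx)
        if cols is None:
            cols = slice(None)
            width = self.p
        else:
            cols = np.asarray(cols, dtype=int)
            width = cols.size
        Xc = self.X[:, cols] if isinstance(cols, np.ndarray) else self.X
        if k == 0:
            d = self.colsq[cols] + 1.0 / self.v
            r = self.Xty[cols].copy()
        else:
            B = self.X[:, idx].T @ Xc  # k x width
            d = (self.colsq[cols] + 1.0 / self.v
                 - np.einsum("kp,kq,qp->p", B, Ainv, B))
            r = self.Xty[cols] - B.T @ c
        bad = ~np.isfinite(d) | (d <= 1e-12)
        d = np.where(bad, 1.0, d)
        s = np.maximum(self.yty - quad0 - r**2 / d, 1e-300)
        vals = (
            self.const
            - 0.5 * ((k + 1) * np.log(self.v) + logdet0 + np.log(d))
            - (self.n / 2.0) * np.log(s)
        )
        vals[bad] = -np.inf
        if isinstance(cols, np.ndarray):
            out = np.full(self.p, -np.inf)
            out[cols] = vals
        else:
            out = vals
        if idx:
            out[idx] = -np.inf
        return out


def model_log_marginal(genotypes, expression, config: FinemapConfig) -> float:
    """Log marginal likelihood of one candidate model (all supplied SNPs).

    Genotype columns and expression are centered and scaled internally.
    Zero-variance or collinear columns are dropped with a warning; the null
    (zero-column) model has the closed-form intercept-only value.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if G.shape[0] == 1 and np.ndim(genotypes) == 1:
        G = G.T
    y = np.asarray(expression, dtype=float)
    y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    k = G.shape[1]
    if k > config.max_model_size:
        raise ValidationError(
            f"model size {k} exceeds max_model_size {config.max_model_size}"
        )
    X, ok = _standardize(G)
    if not ok.all():
        warnings.warn("dropping zero-variance genotype column(s)", stacklevel=2)
        X = X[:, ok]
    # drop columns with no residual variance against those already kept
    kept: list = []
    for j in range(X.shape[1]):
        if kept:
            coef, *_ = np.linalg.lstsq(X[:, kept], X[:, j], rcond=None)
            resid = X[:, j] - X[:, kept] @ coef
            if float(resid @ resid) <= 1e-8 * X.shape[0]:
                warnings.warn("dropping collinear genotype column",
                              stacklevel=2)
                continue
        kept.append(j)
    ev = _Evaluator(X[:, kept], y, config.effect_prior_variance)
    return ev.logml(list(range(len(kept))))


def _search_models(ev: _Evaluator, config: FinemapConfig, log_prior_odds: float):
    """Collect candidate models with their log posterior scores.

    Returns a dict mapping frozenset(SNP indices) -> log score (marginal
    likelihood plus model prior, up to a model-independent constant).
    """
    p = ev.p
    kmax = min(config.max_model_size, p)

    def score(logml, k):
        return logml + k * log_prior_odds

    scored: dict = {frozenset(): score(ev.logml([]), 0)}

    if config.search == "exhaustive":
        n_models = sum(
            int(np.prod([p - i for i in range(k)]) / np.prod(range(1, k + 1)))
            for k in range(1, kmax + 1)
        )
        if n_models > 2_000_000:
            raise ValidationError(
                f"exhaustive enumeration of {n_models} models is impractical; "
                "use greedy-forward search"
            )
        for k in range(1, kmax + 1):
            for combo in itertools.combinations(range(p), k):
                logml = ev.logml(list(combo))
                if np.isfinite(logml):
                    scored[frozenset(combo)] = score(logml, k)
        return scored

    # models further than this below the running best carry no usable mass
    slack = 35.0
    best_seen = [max(scored.values())]
    pool_size = 128

    def record_additions(base: list, cols=None):
        add = ev.eval_additions(base, cols=cols)
        k1 = len(base) + 1
        sc_vec = add + k1 * log_prior_odds
        finite = np.isfinite(add)
        if finite.any():
            best_seen[0] = max(best_seen[0], float(sc_vec[finite].max()))
        keep = finite & (sc_vec > best_seen[0] - slack)
        base_set = frozenset(base)
        for j in np.flatnonzero(keep):
            key = base_set | {int(j)}
            if scored.get(key, -np.inf) < sc_vec[j]:
                scored[key] = sc_vec[j]
        return add

    # forward beam over a conditionally-refreshed candidate pool: at each
    # model size the best base gets a full-width conditional scan (which
    # also tops up the pool, so masked signals can surface), while the
    # remaining beam members are expanded within the pool only
    beam = 8
    add0 = record_additions([])
    order0 = np.argsort(add0)[::-1]
    pool = set(int(j) for j in order0[:pool_size] if np.isfinite(add0[j]))
    frontier: list = [[]] if p > 1 else []
    for size in range(kmax):
        level_new = []
        for rank, base in enumerate(frontier):
            if size == 0 and rank == 0:
                continue  # the empty base was scanned above
            cols = None if rank == 0 else np.fromiter(
                (j for j in sorted(pool) if j not in base), dtype=int)
            if cols is not None and cols.size == 0:
                continue
            add = record_additions(base, cols=cols)
            if rank == 0:
                top = np.argsort(add)[::-1][:64]
                pool.update(int(j) for j in top if np.isfinite(add[j]))
        level = [(k, s) for k, s in scored.items() if len(k) == size + 1]
        if not level:
            break
        level.sort(key=lambda kv: -kv[1])
        if level[0][1] < best_seen[0] - 10.0:
            break  # deeper models carry negligible mass
        frontier = [sorted(k) for k, _ in level[:beam]]
    current = sorted(max(scored.items(), key=lambda kv: kv[1])[0])

    # one-step deletion / swap refinement around the selected model
    for _ in range(2 * max(len(current), 1)):
        if not current:
            break
        cur_score = scored[frozenset(current)]
        best_move, best_score = None, cur_score
        for i in current:
            base = [x for x in current if x != i]
            key = frozenset(base)
            if key not in scored:
                scored[key] = score(ev.logml(base), len(base))
            if scored[key] > best_score:
                best_move, best_score = base, scored[key]
            cols = np.fromiter(
                (j for j in sorted(pool) if j not in base), dtype=int)
            if cols.size == 0:
                continue
            add = record_additions(base, cols=cols)
            jj = int(np.argmax(add))
            sw_score = score(float(add[jj]), len(base) + 1)
            if np.isfinite(add[jj]) and sw_score > best_score:
                best_move, best_score = base + [jj], sw_score
        if best_move is None:
            break
        current = best_move
    return scored


def finemap(
    genotypes,
    expression,
    config: FinemapConfig | None = None,
    snp_ids=None,
    positions=None,
    gene_id: str = "gene",
    tissue: str = "unknown",
) -> GeneAnnotation:
    """Fine-map a gene's cis region and return its probabilistic annotation.

    Posterior model probabilities are normalized over the retained model set
    (null model always included); SNP-level PIPs are membership sums; signal
    clusters are built from the empirical LD of the retained SNPs.
    """
    if config is None:
        config = FinemapConfig()
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(expression, dtype=float)
    n, p = G.shape
    if n != y.shape[0]:
        raise ValidationError("genotype and expression sample sizes differ")
    if n <= config.max_model_size + 2:
        raise ValidationError("too few samples for the requested model size")
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(p)]

    pi1 = config.prior_inclusion if config.prior_inclusion is not None else 1.0 / p
    log_prior_odds = float(np.log(pi1) - np.log1p(-pi1))

    X, ok = _standardize(G)
    ys = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    ev = _Evaluator(X, ys, config.effect_prior_variance)
    if not ok.all():
        # monomorphic SNPs can never enter a model
        ev.colsq = np.where(ok, ev.colsq, -np.inf)

    scored = _search_models(ev, config, log_prior_odds)

    items = sorted(scored.items(), key=lambda kv: -kv[1])
    kept = items[: config.max_models_retained]
    if not any(len(k) == 0 for k, _ in kept):
        kept.append((frozenset(), scored[frozenset()]))
    keys = [k for k, _ in kept]
    logp = np.array([s for _, s in kept])
    post = np.exp(logp - logsumexp(logp))

    models = [
        AssociationModel(frozenset(snp_ids[j] for j in key), float(pr))
        for key, pr in zip(keys, post)
    ]

    pip = np.zeros(p)
    for key, pr in zip(keys, post):
        for j in key:
            pip[j] += pr
    pip = np.minimum(pip, 1.0)

    snps = [
        SnpRecord(
            snp_ids[j],
            int(positions[j]) if positions is not None else j + 1,
            pip=float(pip[j]),
        )
        for j in range(p)
        if pip[j] > 0
    ]

    keep = np.flatnonzero(pip >= config.pip_floor)
    clusters = []
    if keep.size and (1.0 - float(post[[len(k) == 0 for k in keys]].sum())) > 0.01:
        sub = X[:, keep]
        ld = np.corrcoef(sub, rowvar=False)
        ld = np.atleast_2d(ld)
        # posterior co-inclusion over the retained SNPs: separates distinct
        # signals in LD (which co-occur in models) from exchangeable tags
        pos = {int(j): i for i, j in enumerate(keep)}
        co = np.zeros((keep.size, keep.size))
        for key, pr in zip(keys, post):
            ix = [pos[j] for j in key if j in pos]
            if len(ix) > 1 and pr > 0:
                co[np.ix_(ix, ix)] += pr
        clusters = build_clusters(
            pip[keep],
            ld,
            r2_min=config.r2_min,
            pip_floor=config.pip_floor,
            snp_ids=[snp_ids[j] for j in keep],
            coinclusion=co,
        )

    return GeneAnnotation(gene_id, tissue, snps, models, clusters)
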