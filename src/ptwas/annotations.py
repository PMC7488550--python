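"""Probabilistic eQTL annotations.

A Bayesian multi-SNP fine-mapping analysis of a gene's *cis* region yields
three levels of information:

* a set of candidate association models (SNP combinations), each with a
  posterior model probability;
* a posterior inclusion probability (PIP) per SNP, the probability that the
  SNP is a causal eQTL;
* signal clusters: groups of SNPs in tight LD that represent the same
  underlying association signal, summarized by a signal-level PIP (SPIP),
  the sum of member PIPs.

This module holds the in-memory data model for that triple, a reader/writer
for a simple line-oriented text dialect, and the clustering rule that groups
SNPs into signal clusters from PIPs and an LD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParseError, ValidationError

__all__ = [
    "SnpRecord",
    "AssociationModel",
    "SignalCluster",
    "GeneAnnotation",
    "read_annotation",
    "write_annotation",
    "build_clusters",
]


@dataclass(frozen=True)
class SnpRecord:
    """A single candidate SNP with its posterior inclusion probability."""

    snp_id: str
    position: int = 0
    effect_allele: str = "N"
    other_allele: str = "N"
    pip: float = 0.0

    def __post_init__(self):
        if not (-1e-12 <= self.pip <= 1 + 1e-12):
            raise ValidationError(f"PIP of {self.snp_id} outside [0,1]: {self.pip}")


@dataclass(frozen=True)
class AssociationModel:
    """A candidate multi-SNP association model with its posterior probability.

    The empty SNP set denotes the null (no-eQTL) model.
    """

    snp_ids: frozenset
    posterior_prob: float

    def __post_init__(self):
        object.__setattr__(self, "snp_ids", frozenset(self.snp_ids))
        if not (-1e-12 <= self.posterior_prob <= 1 + 1e-12):
            raise ValidationError(
                f"posterior model probability outside [0,1]: {self.posterior_prob}"
            )

    @property
    def is_null(self) -> bool:
        return len(self.snp_ids) == 0


@dataclass
class SignalCluster:
    """A set of LD-linked SNPs representing one independent eQTL signal.

    ``spip`` is the signal-level PIP: the sum of member SNP PIPs. Members are
    ordered by decreasing PIP (ties by SNP id).
    """

    cluster_id: int
    member_snp_ids: list
    spip: float
    member_pips: list | None = None


@dataclass
class GeneAnnotation:
    """The full probabilistic annotation of one gene in one tissue."""

    gene_id: str
    tissue: str = "unknown"
    snps: list = field(default_factory=list)
    models: list = field(default_factory=list)
    clusters: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- convenience accessors -------------------------------------------------
    def pip(self, snp_id: str) -> float:
        return self._pip_map[snp_id]

    @property
    def _pip_map(self) -> dict:
        return {s.snp_id: s.pip for s in self.snps}

    @property
    def snp_ids(self) -> list:
        return [s.snp_id for s in self.snps]

    def model_mass(self) -> float:
        """Total posterior mass over retained models (may be < 1 if truncated)."""
        return float(sum(m.posterior_prob for m in self.models))

    def null_prob(self) -> float:
        """Posterior probability of the null model, explicit plus implicit mass."""
        explicit = sum(m.posterior_prob for m in self.models if m.is_null)
        return float(explicit + max(0.0, 1.0 - self.model_mass()))

    def validate(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate SNP id(s) in annotation: {dup}")
        known = set(ids)
        for m in self.models:
            missing = m.snp_ids - known
            if missing:
                raise ValidationError(
                    f"model references unknown SNP(s): {sorted(missing)}"
                )
        for c in self.clusters:
            missing = set(c.member_snp_ids) - known
            if missing:
                raise ValidationError(
                    f"cluster {c.cluster_id} references unknown SNP(s): {sorted(missing)}"
                )
        mass = self.model_mass()
        if mass > 1 + 1e-6:
            raise ValidationError(f"model posterior mass exceeds 1: {mass}")


def pips_from_models(models) -> dict:
    """SNP-level PIPs as membership sums of posterior model probabilities."""
    pips: dict = {}
    for m in models:
        for sid in m.snp_ids:
            pips[sid] = pips.get(sid, 0.0) + m.posterior_prob
    return pips


# ----------------------------------------------------------------------------
# Signal-cluster construction
# ----------------------------------------------------------------------------

def build_clusters(
    pips,
    ld,
    r2_min: float = 0.25,
    pip_floor: float = 0.01,
    snp_ids=None,
    coinclusion=None,
    coinclusion_max: float = 0.1,
):
    """Group SNPs into LD-based signal clusters.

    Greedy seeding by descending PIP: the highest-PIP unassigned SNP seeds a
    cluster; any SNP whose squared correlation with that seed is at least
    ``r2_min`` joins it. SNPs with PIP below ``pip_floor`` are left out of all
    clusters. The result is a disjoint partition of the retained SNPs, ordered
    by decreasing SPIP.

    A cluster represents one underlying signal, so its members must be
    *exchangeable* explanations of that signal. Two distinct causal signals
    in LD co-occur in high-posterior models, whereas alternative tags of the
    same signal do not; when a ``coinclusion`` matrix (posterior probability
    that both SNPs appear in a model together) is supplied, a SNP joins the
    seed's cluster only if their co-inclusion is small relative to the
    smaller of the two PIPs (< ``coinclusion_max``). This keeps each SPIP a
    probability instead of an expected count over merged signals.

    Parameters
    ----------
    pips : array-like of float
        SNP-level posterior inclusion probabilities, aligned to ``ld`` rows.
    ld : (p, p) array-like
        SNP-by-SNP correlation matrix (signed r; squared internally).
    snp_ids : sequence of str, optional
        Names for cluster membership lists; defaults to ``snp0..snp{p-1}``.
    coinclusion : (p, p) array-like, optional
        Posterior co-inclusion probabilities from the fine-mapping model
        average; omit when only PIPs and LD are available.
    """
    pips = np.asarray(pips, dtype=float)
    ld = np.asarray(ld, dtype=float)
    p = pips.shape[0]
    if ld.shape != (p, p):
        raise ValidationError(f"LD shape {ld.shape} does not match {p} PIPs")
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(p)]
    elif len(snp_ids) != p:
        raise ValidationError("snp_ids length does not match PIP vector")

    # order-invariant processing: descending PIP, ties broken by SNP id
    order = sorted(range(p), key=lambda i: (-pips[i], str(snp_ids[i])))
    eligible = [i for i in order if pips[i] >= pip_floor]

    if coinclusion is not None:
        coinclusion = np.asarray(coinclusion, dtype=float)
        if coinclusion.shape != (p, p):
            raise ValidationError("coinclusion shape does not match PIPs")

    def same_signal(seed, j):
        if j == seed:
            return True
        if coinclusion is None:
            return True
        bound = coinclusion_max * min(pips[seed], pips[j])
        return coinclusion[seed, j] <= max(bound, 1e-12)

    r2 = ld**2
    clusters = []
    assigned = np.zeros(p, dtype=bool)
    for seed in eligible:
        if assigned[seed]:
            continue
        members = [j for j in eligible
                   if not assigned[j] and r2[seed, j] >= r2_min
                   and same_signal(seed, j)]
        for j in members:
            assigned[j] = True
        clusters.append(
            SignalCluster(
                cluster_id=0,
                member_snp_ids=[snp_ids[j] for j in members],
                spip=float(pips[members].sum()),
                member_pips=[float(pips[j]) for j in members],
            )
        )
    clusters.sort(key=lambda c: (-c.spip, c.member_snp_ids[0]))
    for k, c in enumerate(clusters):
        c.cluster_id = k + 1
    return clusters


# ----------------------------------------------------------------------------
# Text dialect reader / writer
# ----------------------------------------------------------------------------
#
#   gene <gene_id> <tissue>
#   M <posterior_prob> <snp1,snp2,...>      ("." or empty list = null model)
#   S <snp_id> <position> <ea> <oa> <pip>   (optional; pip recomputed if absent)
#   C <cluster_id> <spip> <snp1,...>        (optional)


def read_annotation(path) -> GeneAnnotation:
    """Read one gene's annotation from the documented text dialect.

    SNPs that appear in models but have no ``S`` line get a synthetic record
    whose PIP is the membership sum of posterior model probabilities.
    """
    gene_id = None
    tissue = "unknown"
    models: list = []
    snp_meta: dict = {}
    clusters: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            try:
                if tag == "gene":
                    gene_id = parts[1]
                    tissue = parts[2] if len(parts) > 2 else "unknown"
                elif tag == "M":
                    prob = float(parts[1])
                    sids = () if len(parts) < 3 or parts[2] == "." else tuple(
                        parts[2].split(",")
                    )
                    models.append(AssociationModel(frozenset(sids), prob))
                elif tag == "S":
                    sid = parts[1]
                    if sid in snp_meta:
                        raise ValidationError(f"duplicate SNP id: {sid}")
                    snp_meta[sid] = (
                        int(parts[2]),
                        parts[3],
                        parts[4],
                        float(parts[5]),
                    )
                elif tag == "C":
                    clusters.append(
                        SignalCluster(
                            cluster_id=int(parts[1]),
                            member_snp_ids=parts[3].split(","),
                            spip=float(parts[2]),
                        )
                    )
                else:
                    raise ParseError(f"unknown record tag {tag!r}", lineno)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, (ParseError, ValidationError)):
                    raise
                raise ParseError(f"malformed {tag!r} record: {exc}", lineno) from exc
    if gene_id is None:
        raise ParseError("no 'gene' header line found")

    model_pips = pips_from_models(models)
    snps = []
    seen = set()
    for sid, (pos, ea, oa, pip) in snp_meta.items():
        snps.append(SnpRecord(sid, pos, ea, oa, pip))
        seen.add(sid)
    for sid, pip in sorted(model_pips.items()):
        if sid not in seen:
            snps.append(SnpRecord(sid, pip=min(1.0, pip)))
    pip_map = {s.snp_id: s.pip for s in snps}
    for c in clusters:
        if c.member_pips is None:
            try:
                c.member_pips = [pip_map[sid] for sid in c.member_snp_ids]
            except KeyError:
                pass
    return GeneAnnotation(gene_id, tissue, snps, models, clusters)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    """Write all three annotation sections in the text dialect."""
    with open(path, "w") as fh:
        fh.write(f"gene {annotation.gene_id} {annotation.tissue}\n")
        for m in annotation.models:
            sids = ",".join(sorted(m.snp_ids)) if m.snp_ids else "."
            fh.write(f"M {m.posterior_prob:.10g} {sids}\n")
        for s in annotation.snps:
            fh.write(
                f"S {s.snp_id} {s.position} {s.effect_allele} "
                f"{s.other_allele} {s.pip:.10g}\n"
            )
        for c in annotation.clusters:
            fh.write(
                f"C {c.cluster_id} {c.spip:.10g} {','.join(c.member_snp_ids)}\n"
            )
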