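"""Readers, writers, allele harmonization, and the pipeline orchestrator.

On-disk formats (all TSV with headers, tab-separated, versioned header
comment line):

* dosage matrix: rows = SNPs, columns = samples; first column ``snp_id``;
* GWAS summary statistics: ``snp_id effect_allele other_allele z`` with
  optional ``beta se n`` columns;
* composite-IV weights: ``gene tissue snp_id effect_allele weight
  genotype_sd``;
* estimates: ``gene tissue beta se n_instruments Q I2 eligible_clusters``;
* diagnosis: ``gene tissue T Q I2 flagged``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .annotations import GeneAnnotation
from .composite_iv import CompositeIV, build_composite_iv, scan_summary
from .estimation import cluster_estimate, ivw_combine, snp_wald
from .exceptions import (NotEstimable, UndefinedTestError, ValidationError,
                         WeakInstrumentError)
from .finemap import FinemapConfig, finemap
from .heterogeneity import er_diagnose
from .simulate import marginal_stats

FORMAT_VERSION = "ptwas-tsv-v1"

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class RunConfig:
    """Analysis thresholds and knobs, overridable from a YAML key:value file."""

    spip_min: float = 0.50
    i2_exclude: float = 0.5
    fdr_level: float = 0.05
    ld_regularization: float = 0.05
    scan_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("spip_min", "i2_exclude", "fdr_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0,1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_dosages(path):
    """Dosage TSV (snps x samples) -> (n x p matrix, snp_ids, sample_ids)."""
    df = _read_tsv(path)
    if df.columns[0] != "snp_id":
        raise ParseErrorFirstColumn(path)
    snp_ids = df["snp_id"].astype(str).tolist()
    samples = df.columns[1:].tolist()
    G = df.iloc[:, 1:].to_numpy(dtype=float).T
    return G, snp_ids, samples


class ParseErrorFirstColumn(ValidationError):
    def __init__(self, path):
        super().__init__(f"{path}: first column of a dosage TSV must be 'snp_id'")


def write_dosages(path, genotypes, snp_ids, sample_ids) -> None:
    G = np.asarray(genotypes)
    df = pd.DataFrame(G.T, columns=list(sample_ids))
    df.insert(0, "snp_id", list(snp_ids))
    _write_tsv(df, path)


def read_sumstats(path) -> pd.DataFrame:
    """GWAS summary statistics; derives z from beta/se when absent."""
    df = _read_tsv(path)
    required = {"snp_id", "effect_allele", "other_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sumstats missing column(s): {sorted(missing)}")
    if "z" not in df.columns:
        if {"beta", "se"} <= set(df.columns):
            df["z"] = df["beta"] / df["se"]
        else:
            raise ValidationError("sumstats need a z column or beta + se")
    if not np.all(np.isfinite(df["z"])):
        raise ValidationError("non-finite z in sumstats")
    return df


def write_weights(path, civs) -> None:
    rows = []
    for civ in civs:
        for s, w, sd in zip(civ.snp_ids, civ.weights, civ.genotype_sd):
            rows.append((civ.gene_id, civ.tissue, s, "N", w, sd))
    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["gene", "tissue", "snp_id", "effect_allele",
                     "weight", "genotype_sd"],
        ),
        path,
    )


def read_weights(path):
    """Weight TSV -> list of CompositeIV (one per gene-tissue pair)."""
    df = _read_tsv(path)
    civs = []
    for (gene, tissue), grp in df.groupby(["gene", "tissue"], sort=False):
        civs.append(
            CompositeIV(
                str(gene),
                str(tissue),
                grp["snp_id"].astype(str).tolist(),
                grp["weight"].to_numpy(dtype=float),
                grp["genotype_sd"].to_numpy(dtype=float),
            )
        )
    return civs


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(sumstats: pd.DataFrame, annotation_snps):
    """Align GWAS z-scores to annotation SNPs (effect-allele orientation).

    Matching is by snp_id. z is sign-flipped when the GWAS effect allele is
    the annotation's other allele; strand-ambiguous SNPs (A/T, C/G) and
    unmatched or allele-incompatible SNPs are dropped. Returns
    ``(z_by_snp_id dict, log dict)`` where the log counts matches, flips,
    ambiguous and unmatched drops.
    """
    ss = sumstats.set_index(sumstats["snp_id"].astype(str))
    z_out: dict = {}
    log = {"matched": 0, "flipped": 0, "ambiguous": 0,
           "unmatched": 0, "mismatched": 0}
    for snp in annotation_snps:
        sid, ea, oa = snp.snp_id, snp.effect_allele.upper(), snp.other_allele.upper()
        if sid not in ss.index:
            log["unmatched"] += 1
            continue
        row = ss.loc[sid]
        g_ea = str(row["effect_allele"]).upper()
        g_oa = str(row["other_allele"]).upper()
        if frozenset((g_ea, g_oa)) in _AMBIGUOUS:
            log["ambiguous"] += 1
            continue
        if (g_ea, g_oa) == (ea, oa) or ea == "N":
            z_out[sid] = float(row["z"])
            log["matched"] += 1
        elif (g_ea, g_oa) == (oa, ea):
            z_out[sid] = -float(row["z"])
            log["matched"] += 1
            log["flipped"] += 1
        else:
            log["mismatched"] += 1
    if not z_out:
        raise ValidationError("no SNP in the summary statistics matches the "
                              "annotation (after harmonization)")
    return z_out, log


# ---------------------------------------------------------------------------
# pipeline orchestrator
# ---------------------------------------------------------------------------

@dataclass
class GeneData:
    """Per-gene inputs for the pipeline: eQTL panel data plus identifiers."""

    gene_id: str
    genotypes: np.ndarray  # eQTL reference panel, n x p dosages
    expression: np.ndarray | None = None
    snp_ids: list = field(default_factory=list)
    tissue: str = "unknown"
    annotation: GeneAnnotation | None = None


def run_pipeline(config: RunConfig, genes, sumstats: pd.DataFrame):
    """Scan -> exclusion-restriction validation -> estimation, per gene.

    For each :class:`GeneData`: fine-map (unless an annotation is supplied),
    build the composite IV, harmonize GWAS z-scores, run the
    summary-statistic scan; genes passing at ``scan_alpha`` proceed to
    cluster-level estimation and I2 diagnosis; genes with I2 above
    ``i2_exclude`` are flagged and excluded from the estimate table.

    Returns dict with ``scan``, ``diagnosis``, ``estimates`` DataFrames and
    a ``counts`` log (conserved: genes_in = scan_failed + scan_not_passed +
    flagged + estimated + not_estimable).
    """
    scan_rows, diag_rows, est_rows = [], [], []
    counts = {"genes_in": 0, "scan_failed": 0, "scan_not_passed": 0,
              "flagged": 0, "estimated": 0, "not_estimable": 0}
    has_beta_se = {"beta", "se"} <= set(sumstats.columns)

    for gd in genes:
        counts["genes_in"] += 1
        gene, tissue = gd.gene_id, gd.tissue
        try:
            ann = gd.annotation
            if ann is None:
                ann = finemap(
                    gd.genotypes, gd.expression, FinemapConfig(),
                    snp_ids=gd.snp_ids or None, gene_id=gene, tissue=tissue,
                )
            civ = build_composite_iv(
                ann, gd.genotypes, gd.expression
                if gd.expression is not None else np.zeros(gd.genotypes.shape[0]),
                snp_ids=gd.snp_ids or None,
            )
            snp_recs = {s.snp_id: s for s in ann.snps}
            z_map, _ = harmonize_alleles(
                sumstats, [snp_recs.get(s) for s in civ.snp_ids if s in snp_recs]
            )
            keep = [i for i, s in enumerate(civ.snp_ids) if s in z_map]
            if not keep:
                raise ValidationError("no scannable SNPs after harmonization")
            sub_ids = [civ.snp_ids[i] for i in keep]
            sub_civ = CompositeIV(gene, tissue, sub_ids,
                                  civ.weights[keep], civ.genotype_sd[keep])
            col = {s: j for j, s in enumerate(gd.snp_ids)} if gd.snp_ids else {
                s: int(s[3:]) for s in sub_ids}
            idx = [col[s] for s in sub_ids]
            panel = gd.genotypes[:, idx].astype(float)
            ld = np.atleast_2d(np.corrcoef(panel, rowvar=False))
            ld = np.nan_to_num(ld, nan=0.0)
            np.fill_diagonal(ld, 1.0)
            z_vec = np.array([z_map[s] for s in sub_ids])
            scan = scan_summary(sub_civ, z_vec, ld,
                                ld_regularization=config.ld_regularization)
        except (ValidationError, WeakInstrumentError,
                UndefinedTestError) as exc:
            counts["scan_failed"] += 1
            scan_rows.append({"gene": gene, "tissue": tissue, "z": np.nan,
                              "p_value": np.nan, "error": str(exc)})
            continue
        scan_rows.append({"gene": gene, "tissue": tissue, "z": scan.z,
                          "p_value": scan.p_value, "error": ""})
        if scan.p_value > config.scan_alpha:
            counts["scan_not_passed"] += 1
            continue

        ests = _cluster_estimates(gd, ann, sumstats, has_beta_se)
        het = er_diagnose(ests, spip_min=config.spip_min)
        flagged = het is not None and het.i2 > config.i2_exclude
        if het is not None:
            diag_rows.append({"gene": gene, "tissue": tissue, "T": het.t,
                              "Q": het.q, "I2": het.i2, "flagged": flagged})
        if flagged:
            counts["flagged"] += 1
            continue
        try:
            eff = ivw_combine(ests, spip_min=config.spip_min,
                              gene_id=gene, tissue=tissue)
        except NotEstimable:
            counts["not_estimable"] += 1
            continue
        counts["estimated"] += 1
        est_rows.append({
            "gene": gene, "tissue": tissue, "beta": eff.beta, "se": eff.se,
            "n_instruments": eff.n_instruments, "Q": eff.q_stat, "I2": eff.i2,
            "eligible_clusters": eff.n_instruments,
        })

    return {
        "scan": pd.DataFrame(scan_rows),
        "diagnosis": pd.DataFrame(
            diag_rows, columns=["gene", "tissue", "T", "Q", "I2", "flagged"]),
        "estimates": pd.DataFrame(
            est_rows, columns=["gene", "tissue", "beta", "se", "n_instruments",
                               "Q", "I2", "eligible_clusters"]),
        "counts": counts,
    }


def _cluster_estimates(gd: GeneData, ann: GeneAnnotation,
                       sumstats: pd.DataFrame, has_beta_se: bool):
    """Per-cluster Wald/BMA estimates for one gene from panel + sumstats."""
    if gd.expression is None:
        return []
    col = ({s: j for j, s in enumerate(gd.snp_ids)} if gd.snp_ids
           else {s.snp_id: int(s.snp_id[3:]) for s in ann.snps})
    need = sorted({s for c in ann.clusters for s in c.member_snp_ids
                   if s in col}, key=lambda s: col[s])
    if not need:
        return []
    idx = [col[s] for s in need]
    eb, ese = marginal_stats(gd.genotypes[:, idx], gd.expression)
    eqtl = {s: (eb[i], ese[i]) for i, s in enumerate(need)}
    ss = sumstats.set_index(sumstats["snp_id"].astype(str))
    ests = []
    for c in ann.clusters:
        walds, kept_pips, kept_ids = [], [], []
        for sid, pip in zip(c.member_snp_ids, c.member_pips or []):
            if sid not in eqtl or sid not in ss.index:
                continue
            row = ss.loc[sid]
            if has_beta_se:
                bg, seg = float(row["beta"]), float(row["se"])
            else:
                # unit-scaled fallback: z with unit SE (relative effects only)
                bg, seg = float(row["z"]), 1.0
            be, see = eqtl[sid]
            if not np.isfinite(see):
                continue
            try:
                walds.append(snp_wald(bg, seg, be, see, sid))
            except WeakInstrumentError:
                continue
            kept_pips.append(pip)
            kept_ids.append(sid)
        if not walds:
            continue
        from .annotations import SignalCluster

        sub = SignalCluster(c.cluster_id, kept_ids, c.spip,
                            member_pips=kept_pips)
        ests.append(cluster_estimate(sub, walds))
    return ests


def write_estimates(path, estimates: pd.DataFrame) -> None:
    _write_tsv(estimates, path)


def write_diagnosis(path, diagnosis: pd.DataFrame) -> None:
    _write_tsv(diagnosis, path)


def write_global_scan(path, records) -> None:
    rows = []
    for r in records:
        tissues = list(r.per_tissue_p)
        pmin = min(r.per_tissue_p.values())
        tmin = min(r.per_tissue_p, key=r.per_tissue_p.get)
        rows.append((r.gene_id, r.acat_p, r.q_value, len(tissues), tmin, pmin))
    _write_tsv(
        pd.DataFrame(rows, columns=["gene", "acat_p", "q_value", "n_tissues",
                                    "min_tissue", "min_p"]),
        path,
    )
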