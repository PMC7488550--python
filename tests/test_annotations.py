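"""Annotation data model, file dialect, and signal-cluster construction."""

import numpy as np
import pytest

from ptwas.annotations import (
    AssociationModel,
    GeneAnnotation,
    SnpRecord,
    build_clusters,
    pips_from_models,
    read_annotation,
    write_annotation,
)
from ptwas.exceptions import ParseError, ValidationError


class TestReadWrite:
    def test_single_model_certainty(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("gene g1 blood\nM 1.0 s1\nS s1 100 A G 1.0\nC 1 1.0 s1\n")
        ann = read_annotation(f)
        assert ann.gene_id == "g1" and ann.tissue == "blood"
        assert ann.pip("s1") == 1.0
        assert len(ann.clusters) == 1 and ann.clusters[0].spip == 1.0

    def test_probabilities_partition_across_models(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("gene g1 blood\nM 0.6 s1\nM 0.4 s2\n")
        ann = read_annotation(f)
        assert ann.pip("s1") == pytest.approx(0.6)
        assert ann.pip("s2") == pytest.approx(0.4)

    def test_pips_equal_membership_sums_on_toy_file(self, tmp_path):
        # oracle: explicit membership-sum over the listed models
        models = [
            ("0.30", "s1"), ("0.25", "s1,s2"), ("0.15", "s3"),
            ("0.10", "s2,s4"), ("0.10", "s5"), ("0.10", "."),
        ]
        f = tmp_path / "a.txt"
        f.write_text(
            "gene g2 lung\n" + "".join(f"M {p} {s}\n" for p, s in models)
        )
        ann = read_annotation(f)
        expected = {}
        for prob, sids in models:
            if sids == ".":
                continue
            for s in sids.split(","):
                expected[s] = expected.get(s, 0.0) + float(prob)
        for sid, pip in expected.items():
            assert ann.pip(sid) == pytest.approx(pip, abs=1e-12)

    def test_round_trip_identity(self, tmp_path, toy_annotation):
        ld = np.eye(5)
        toy_annotation.clusters = build_clusters(
            [s.pip for s in toy_annotation.snps], ld,
            snp_ids=[s.snp_id for s in toy_annotation.snps],
        )
        path = tmp_path / "out.txt"
        write_annotation(toy_annotation, path)
        back = read_annotation(path)
        assert back.gene_id == toy_annotation.gene_id
        assert {m.snp_ids: m.posterior_prob for m in back.models} == pytest.approx(
            {m.snp_ids: m.posterior_prob for m in toy_annotation.models}
        )
        assert {s.snp_id: s.pip for s in back.snps} == pytest.approx(
            {s.snp_id: s.pip for s in toy_annotation.snps}
        )
        assert [c.member_snp_ids for c in back.clusters] == [
            c.member_snp_ids for c in toy_annotation.clusters
        ]

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("gene g1 blood\nM notaprob s1\n")
        with pytest.raises(ParseError, match="line 2"):
            read_annotation(f)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text(
            "gene g1 blood\nM 1.0 s1\nS s1 1 A G 1.0\nS s1 2 A G 0.5\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_annotation(f)

    def test_unknown_tag_rejected(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("gene g1 blood\nX whatever\n")
        with pytest.raises(ParseError):
            read_annotation(f)


class TestInvariants:
    def test_model_mass_cannot_exceed_one(self):
        with pytest.raises(ValidationError):
            GeneAnnotation(
                "g", "t",
                snps=[SnpRecord("s1")],
                models=[AssociationModel(frozenset({"s1"}), 0.7),
                        AssociationModel(frozenset(), 0.5)],
            )

    def test_model_referencing_unknown_snp_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            GeneAnnotation(
                "g", "t", snps=[],
                models=[AssociationModel(frozenset({"s1"}), 0.5)],
            )

    def test_spip_sum_bounded_by_expected_signal_count(self, toy_annotation):
        # sum of cluster SPIPs <= sum_i P(M_i) |M_i|
        pips = [s.pip for s in toy_annotation.snps]
        clusters = build_clusters(
            pips, np.eye(5), snp_ids=[s.snp_id for s in toy_annotation.snps]
        )
        expected_signals = sum(
            m.posterior_prob * len(m.snp_ids) for m in toy_annotation.models
        )
        assert sum(c.spip for c in clusters) <= expected_signals + 1e-6

    def test_null_prob_includes_truncated_mass(self):
        ann = GeneAnnotation(
            "g", "t", snps=[SnpRecord("s1")],
            models=[AssociationModel(frozenset({"s1"}), 0.6)],
        )
        assert ann.null_prob() == pytest.approx(0.4)


class TestBuildClusters:
    def test_perfect_proxies_merge(self):
        ld = np.array([[1.0, 1.0], [1.0, 1.0]])
        cl = build_clusters([0.5, 0.5], ld)
        assert len(cl) == 1
        assert cl[0].spip == pytest.approx(1.0)

    def test_independent_signals_split(self):
        cl = build_clusters([0.9, 0.9], np.eye(2))
        assert len(cl) == 2
        assert [c.spip for c in cl] == pytest.approx([0.9, 0.9])

    def test_block_diagonal_matches_connected_components(self, rng):
        # oracle: connected components of the r2 >= r2_min graph among
        # pip >= pip_floor SNPs; a block-diagonal LD gives one per block
        r = 0.8
        block = np.full((5, 5), r) + (1 - r) * np.eye(5)
        ld = np.block(
            [[block, np.zeros((5, 5))], [np.zeros((5, 5)), block]]
        )
        pips = np.array([0.5, 0.2, 0.1, 0.05, 0.05, 0.4, 0.3, 0.2, 0.05, 0.02])
        clusters = build_clusters(pips, ld, r2_min=0.25, pip_floor=0.01)
        assert len(clusters) == 2
        members = [set(c.member_snp_ids) for c in clusters]
        assert {f"snp{i}" for i in range(5)} in members
        assert {f"snp{i}" for i in range(5, 10)} in members

    def test_pip_floor_excludes_snps(self):
        cl = build_clusters([0.9, 0.005], np.eye(2), pip_floor=0.01)
        assert len(cl) == 1
        assert cl[0].member_snp_ids == ["snp0"]

    def test_input_order_invariance(self, rng):
        p = 12
        A = rng.normal(size=(60, p))
        ld = np.corrcoef(A, rowvar=False)
        pips = rng.uniform(0, 0.4, p)
        ids = [f"rs{i}" for i in range(p)]
        base = build_clusters(pips, ld, snp_ids=ids)
        perm = rng.permutation(p)
        permuted = build_clusters(
            pips[perm], ld[np.ix_(perm, perm)], snp_ids=[ids[i] for i in perm]
        )
        assert [sorted(c.member_snp_ids) for c in base] == [
            sorted(c.member_snp_ids) for c in permuted
        ]

    def test_clusters_disjoint_and_spip_is_member_sum(self, rng):
        p = 20
        A = rng.normal(size=(80, p))
        ld = np.corrcoef(A, rowvar=False)
        pips = rng.uniform(0, 1, p)
        clusters = build_clusters(pips, ld)
        seen = set()
        for c in clusters:
            assert not (set(c.member_snp_ids) & seen)
            seen |= set(c.member_snp_ids)
            assert c.spip == pytest.approx(sum(c.member_pips), abs=1e-8)

    def test_coinclusion_splits_distinct_signals_in_ld(self):
        # two near-certain signals in strong LD co-occur in models: they
        # are separate instruments, not exchangeable tags of one signal
        ld = np.array([[1.0, 0.9], [0.9, 1.0]])
        pips = [0.95, 0.9]
        co = np.array([[0.95, 0.86], [0.86, 0.9]])
        split = build_clusters(pips, ld, coinclusion=co)
        assert len(split) == 2
        assert all(c.spip <= 1.0 + 1e-9 for c in split)
        # exchangeable tags (never co-included) still merge
        merged = build_clusters(pips, ld, coinclusion=np.zeros((2, 2)))
        assert len(merged) == 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            build_clusters([0.5, 0.5], np.eye(3))


def test_pips_from_models_matches_enumeration():
    models = [
        AssociationModel(frozenset({"a", "b"}), 0.4),
        AssociationModel(frozenset({"a"}), 0.3),
        AssociationModel(frozenset(), 0.3),
    ]
    pips = pips_from_models(models)
    assert pips == pytest.approx({"a": 0.7, "b": 0.4})
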