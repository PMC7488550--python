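"""Composite-IV construction, scan tests, and weight-sparsity summary."""

import numpy as np
import pytest
from scipy import stats

from ptwas.annotations import AssociationModel, GeneAnnotation, SnpRecord
from ptwas.composite_iv import (
    CompositeIV,
    build_composite_iv,
    gini,
    scan_individual,
    scan_summary,
)
from ptwas.exceptions import UndefinedTestError, ValidationError


def _annotation(models, n_snps=5):
    snps = [SnpRecord(f"snp{j}") for j in range(n_snps)]
    return GeneAnnotation("g", "t", snps, models, [])


def _ols(X, y):
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)


class TestBuildCompositeIV:
    def test_single_model_gives_its_ols_slope(self, rng):
        G = rng.integers(0, 3, size=(200, 5)).astype(float)
        y = 0.8 * G[:, 0] + rng.standard_normal(200)
        ann = _annotation([AssociationModel(frozenset({"snp0"}), 1.0)])
        civ = build_composite_iv(ann, G, y)
        slope = _ols(G[:, [0]], y)[0]
        w = dict(zip(civ.snp_ids, civ.weights))
        assert w["snp0"] == pytest.approx(slope)
        assert all(v == 0 for k, v in w.items() if k != "snp0")

    def test_two_model_average(self, rng):
        # w_j = sum_i P(M_i) beta_hat_{M_i, j}, by hand
        G = rng.integers(0, 3, size=(300, 2)).astype(float)
        y = rng.standard_normal(300)
        ann = _annotation(
            [AssociationModel(frozenset({"snp0"}), 0.5),
             AssociationModel(frozenset({"snp1"}), 0.5)],
            n_snps=2,
        )
        civ = build_composite_iv(ann, G, y)
        w = dict(zip(civ.snp_ids, civ.weights))
        assert w["snp0"] == pytest.approx(0.5 * _ols(G[:, [0]], y)[0])
        assert w["snp1"] == pytest.approx(0.5 * _ols(G[:, [1]], y)[0])

    def test_ensemble_identity(self, rng):
        # oracle: sum_j w_j G_j == sum_i P(M_i) xhat_{M_i} evaluated directly
        G = rng.integers(0, 3, size=(150, 5)).astype(float)
        y = G[:, 1] - 0.5 * G[:, 3] + rng.standard_normal(150)
        models = [
            AssociationModel(frozenset({"snp1"}), 0.4),
            AssociationModel(frozenset({"snp1", "snp3"}), 0.35),
            AssociationModel(frozenset({"snp2"}), 0.15),
            AssociationModel(frozenset(), 0.1),
        ]
        ann = _annotation(models)
        civ = build_composite_iv(ann, G, y)
        xhat = civ.predict(G, snp_ids=[f"snp{j}" for j in range(5)])
        Gc = G - G.mean(axis=0)
        direct = np.zeros(150)
        for m in models:
            if m.is_null:
                continue
            idx = sorted(int(s[3:]) for s in m.snp_ids)
            beta = _ols(G[:, idx], y)
            direct += m.posterior_prob * (Gc[:, idx] @ beta)
        xhat_c = xhat - xhat.mean()
        assert np.allclose(xhat_c, direct, atol=1e-10)

    def test_unknown_snp_rejected(self, rng):
        G = rng.integers(0, 3, size=(50, 2)).astype(float)
        ann = GeneAnnotation(
            "g", "t", [SnpRecord("rs99")],
            [AssociationModel(frozenset({"rs99"}), 1.0)], [],
        )
        with pytest.raises(ValidationError, match="missing"):
            build_composite_iv(ann, G, rng.standard_normal(50))


class TestScanIndividual:
    def test_null_pvalues_uniform(self, rng):
        # calibration: trait independent of the composite IV
        n, reps = 150, 400
        civ = CompositeIV("g", "t", ["snp0"], [1.0], [1.0])
        pvals = []
        for _ in range(reps):
            G = rng.integers(0, 3, size=(n, 1)).astype(float)
            y = rng.standard_normal(n)
            pvals.append(scan_individual(civ, G, y).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_association_no_overflow(self, rng):
        G = rng.integers(0, 3, size=(100, 1)).astype(float)
        civ = CompositeIV("g", "t", ["snp0"], [1.0], [1.0])
        res = scan_individual(civ, G, G[:, 0].copy())
        assert 0.0 < res.p_value <= 1e-250
        assert np.isfinite(res.z) or np.isinf(res.z)

    def test_matches_textbook_ols_t_test(self, rng):
        n = 306
        G = rng.integers(0, 3, size=(n, 3)).astype(float)
        w = np.array([0.6, 0.0, -0.3])
        civ = CompositeIV("g", "t", [f"snp{j}" for j in range(3)], w,
                          G.std(axis=0))
        y = G @ w + rng.standard_normal(n)
        res = scan_individual(civ, G, y)
        # oracle: statsmodels-free longhand OLS t statistic
        x = G @ w
        xc, yc = x - x.mean(), y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        resid = yc - slope * xc
        se = np.sqrt(resid @ resid / (n - 2) / (xc @ xc))
        assert res.z == pytest.approx(slope / se)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(res.z)))

    def test_zero_variance_iv_rejected(self):
        civ = CompositeIV("g", "t", ["snp0"], [0.0], [1.0])
        with pytest.raises(UndefinedTestError):
            scan_individual(civ, np.ones((50, 1)), np.zeros(50))


class TestScanSummary:
    def test_single_snp_passthrough(self):
        civ = CompositeIV("g", "t", ["snp0"], [2.0], [0.5])
        res = scan_summary(civ, [3.1], np.eye(1), ld_regularization=0.0)
        assert res.z == pytest.approx(3.1)

    def test_independent_equal_weights_sum(self):
        civ = CompositeIV("g", "t", ["a", "b"], [1.0, 1.0], [1.0, 1.0])
        res = scan_summary(civ, [2.0, 2.0], np.eye(2), ld_regularization=0.0)
        assert res.z == pytest.approx(2 * np.sqrt(2))

    def test_agrees_with_individual_level_scan(self, rng):
        # oracle: individual-level scan on the panel the LD came from
        n, p = 500, 20
        L = np.linalg.cholesky(0.5 * np.eye(p) + 0.5)
        G = (rng.standard_normal((n, p)) @ L.T > 0.3).astype(float) + (
            rng.standard_normal((n, p)) @ L.T > 0.3
        ).astype(float)
        w = np.zeros(p)
        w[[2, 7, 11]] = [0.8, -0.5, 0.3]
        y = G @ w + rng.standard_normal(n) * 2.0
        ids = [f"snp{j}" for j in range(p)]
        civ = CompositeIV("g", "t", ids, w, G.std(axis=0))
        indiv = scan_individual(civ, G, y)
        beta = np.empty(p)
        se = np.empty(p)
        Gc = G - G.mean(axis=0)
        yc = y - y.mean()
        for j in range(p):
            sxx = Gc[:, j] @ Gc[:, j]
            beta[j] = Gc[:, j] @ yc / sxx
            rss = yc @ yc - beta[j] ** 2 * sxx
            se[j] = np.sqrt(rss / (n - 2) / sxx)
        summ = scan_summary(civ, beta / se, np.corrcoef(G, rowvar=False),
                            ld_regularization=0.0)
        assert abs(summ.z - indiv.z) < 0.2

    def test_inconsistent_ld_rejected(self):
        civ = CompositeIV("g", "t", ["a", "b"], [1.0, -1.0], [1.0, 1.0])
        bad_ld = np.array([[1.0, 2.0], [2.0, 1.0]])  # not a correlation
        with pytest.raises(UndefinedTestError, match="regulariz"):
            scan_summary(civ, [1.0, 1.0], bad_ld, ld_regularization=0.0)


class TestGini:
    def test_point_mass(self):
        assert gini([1.0, 0.0, 0.0, 0.0]) == pytest.approx(0.75)

    def test_perfect_equality(self):
        assert gini([0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_lorenz_curve_oracle(self, rng):
        w = rng.exponential(size=100) * rng.choice([-1, 1], 100)
        g = gini(w)
        a = np.sort(np.abs(w))
        # Lorenz-curve integration: G = 1 - 2 * area under Lorenz curve
        cum = np.concatenate([[0.0], np.cumsum(a)]) / a.sum()
        area = np.trapezoid(cum, dx=1.0 / 100)
        assert g == pytest.approx(1.0 - 2.0 * area, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            gini([0.0, 0.0])
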