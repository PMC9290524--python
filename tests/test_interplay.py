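import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foragenet import interplay
from foragenet.errors import (
    ConstantFactorError,
    InvalidConfigError,
    RankDeficientDesignError,
)


def samples(n):
    return [f"s{j + 1}" for j in range(n)]


class TestModuleFactorCorrelations:
    def build(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=n)
        factors = pd.DataFrame({"f1": f, "f2": rng.normal(size=n)}, index=samples(n))
        eig = pd.DataFrame([f, -f], index=["m1", "m2"], columns=samples(n))
        return eig, factors

    def test_exact_correlations(self):
        eig, factors = self.build()
        table = interplay.module_factor_correlations(eig, factors)
        assert table.r.loc["m1", "f1"] == pytest.approx(1.0)
        assert table.r.loc["m2", "f1"] == pytest.approx(-1.0)
        assert table.p.loc["m1", "f1"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_value_bookkeeping(self):
        eig, factors = self.build()
        factors.loc["s3", "f2"] = np.nan
        table = interplay.module_factor_correlations(eig, factors)
        assert table.n.loc["m1", "f2"] == 19
        assert table.n.loc["m1", "f1"] == 20

    def test_constant_factor_cell_is_missing(self):
        eig, factors = self.build()
        factors["f2"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            table = interplay.module_factor_correlations(eig, factors)
        assert np.isnan(table.r.loc["m1", "f2"])


class TestDropCollinear:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=30)
        factors = pd.DataFrame(
            {"a": f, "b": f.copy(), "c": rng.normal(size=30)}, index=samples(30)
        )
        retained, log = interplay.drop_collinear_factors(factors)
        assert retained == ["a", "c"]
        assert log[0][:2] == ("a", "b")

    def test_boundary_is_inclusive_at_0_9(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=500)
        z = (z - z.mean()) / z.std()
        noise = rng.normal(size=500)
        noise -= z * (noise @ z) / (z @ z)
        noise /= noise.std()
        pair89 = 0.89 * z + np.sqrt(1 - 0.89**2) * noise
        factors = pd.DataFrame({"a": z, "b": pair89}, index=samples(500))
        retained, _ = interplay.drop_collinear_factors(factors, r_cut=0.9)
        assert retained == ["a", "b"]  # |r| = 0.89 < 0.9: both kept

    def test_chain_rule_keeps_ends(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=2000)
        b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.normal(size=2000)
        c = 0.95 * b + np.sqrt(1 - 0.95**2) * rng.normal(size=2000)
        factors = pd.DataFrame({"a": a, "b": b, "c": c}, index=samples(2000))
        corr = factors.corr()
        assert abs(corr.loc["a", "b"]) >= 0.9 and abs(corr.loc["b", "c"]) >= 0.9
        assert abs(corr.loc["a", "c"]) < 0.9
        retained, log = interplay.drop_collinear_factors(factors, r_cut=0.9)
        assert retained == ["a", "c"]
        assert [entry[1] for entry in log] == ["b"]


class TestStandardizeMinmax:
    def test_hand_examples(self):
        assert np.allclose(
            interplay.standardize_minmax(np.array([0.0, 5.0, 10.0])), [-50, 0, 50]
        )
        assert np.allclose(
            interplay.standardize_minmax(np.array([1.0, 2.0, 4.0])),
            [-50.0, -50.0 + 100.0 / 3.0, 50.0],
        )

    def test_idempotent_on_canonical_range(self):
        v = np.array([-50.0, -10.0, 0.0, 50.0])
        assert np.allclose(interplay.standardize_minmax(v), v)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_affine_map_preserves_correlations(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r_before = np.corrcoef(x, y)[0, 1]
        r_after = np.corrcoef(
            interplay.standardize_minmax(x), interplay.standardize_minmax(y)
        )[0, 1]
        assert r_after == pytest.approx(r_before, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantFactorError):
            interplay.standardize_minmax(np.ones(5))


class TestRegression:
    def test_identity_fit(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=40)
        factors = pd.DataFrame(
            {"f1": interplay.standardize_minmax(f)}, index=samples(40)
        )
        eig = pd.Series(interplay.standardize_minmax(f), index=samples(40))
        fit = interplay.fit_module_regression(eig, factors)
        assert fit.coefficient("f1") == pytest.approx(1.0)
        assert fit.coefficient("Intercept") == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_difference_design(self):
        n = 64
        f1 = np.tile([1.0, -1.0], n // 2)
        f2 = np.repeat([1.0, -1.0], n // 2)
        factors = pd.DataFrame({"f1": f1, "f2": f2}, index=samples(n))
        eig = pd.Series(f1 - f2, index=samples(n))
        fit = interplay.fit_module_regression(eig, factors)
        assert fit.coefficient("f1") == pytest.approx(1.0)
        assert fit.coefficient("f2") == pytest.approx(-1.0)

    def test_null_r_squared_small(self):
        rng = np.random.default_rng(5)
        factors = pd.DataFrame(
            rng.normal(size=(200, 5)), index=samples(200), columns=list("abcde")
        )
        eig = pd.Series(rng.normal(size=200), index=samples(200))
        fit = interplay.fit_module_regression(eig, factors)
        assert fit.r_squared < 0.1

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(size=50)
        factors = pd.DataFrame(X, index=samples(50), columns=["a", "b", "c"])
        eig = pd.Series(y, index=samples(50))
        fit = interplay.fit_module_regression(eig, factors)
        design = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        fitted = [fit.coefficient("Intercept")] + [
            fit.coefficient(c) for c in ["a", "b", "c"]
        ]
        assert np.allclose(fitted, beta, atol=1e-10)

    def test_rank_deficient_design_named_error(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=30)
        factors = pd.DataFrame({"a": f, "b": 2 * f}, index=samples(30))
        eig = pd.Series(rng.normal(size=30), index=samples(30))
        with pytest.raises(RankDeficientDesignError):
            interplay.fit_module_regression(eig, factors)

    def test_stars_match_significance_codes(self):
        assert interplay._stars(0.04) == "*"
        assert interplay._stars(0.004) == "**"
        assert interplay._stars(0.0004) == "***"
        assert interplay._stars(0.2) == ""


class TestBiplot:
    def test_identical_rows_identical_scores(self):
        r = pd.DataFrame(
            [[0.5, -0.2], [0.5, -0.2], [-0.1, 0.8]],
            index=["m1", "m2", "m3"],
            columns=["f1", "f2"],
        )
        table = interplay.CorrelationTable(r=r, p=r * 0, n=r * 0 + 10)
        biplot = interplay.correlation_pca_biplot(table)
        assert np.allclose(
            biplot.module_scores.loc["m1"], biplot.module_scores.loc["m2"]
        )

    def test_rank_one_matrix_concentrates_variance(self):
        base = np.array([0.9, -0.3, 0.1])
        r = pd.DataFrame(
            np.outer([1.0, 0.5, -1.0], base),
            index=["m1", "m2", "m3"],
            columns=["f1", "f2", "f3"],
        )
        table = interplay.CorrelationTable(r=r, p=r * 0, n=r * 0 + 10)
        biplot = interplay.correlation_pca_biplot(table)
        assert biplot.variance_fractions[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        r = pd.DataFrame(
            [[0.8, -0.1], [0.2, 0.5], [-0.6, 0.3]],
            index=["m1", "m2", "m3"],
            columns=["f1", "f2"],
        )
        table = interplay.CorrelationTable(r=r, p=r * 0, n=r * 0 + 10)
        biplot = interplay.correlation_pca_biplot(table)
        centered = r.to_numpy() - r.to_numpy().mean(0)
        vals = np.linalg.eigvalsh(centered.T @ centered)[::-1]
        assert np.allclose(
            biplot.variance_fractions, vals[:2] / vals.sum(), atol=1e-10
        )
        # scores reproduce the centered matrix through the loadings
        recon = biplot.module_scores.to_numpy() @ biplot.factor_loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-10)

    def test_too_few_modules_rejected(self):
        r = pd.DataFrame([[0.1, 0.2]], index=["m1"], columns=["f1", "f2"])
        table = interplay.CorrelationTable(r=r, p=r * 0, n=r * 0 + 10)
        with pytest.raises(InvalidConfigError):
            interplay.correlation_pca_biplot(table)


class TestCrossCorrelation:
    def test_source_equal_to_target(self):
        rng = np.random.default_rng(8)
        eig = rng.normal(size=30)
        from tests.conftest import make_expression

        expr = make_expression(np.vstack([eig, eig]))
        target = pd.Series(eig, index=expr.sample_ids)
        per_gene, counts, hist = interplay.gene_eigengene_crosscorrelation(
            expr, expr.gene_ids, target
        )
        assert np.allclose(per_gene["r"], 1.0)
        assert counts.loc[0.01, "positive"] == 2
        assert hist["count"].sum() == 2

    def test_null_calibration(self):
        from tests.conftest import make_expression

        rng = np.random.default_rng(9)
        expr = make_expression(rng.normal(size=(400, 100)))
        target = pd.Series(rng.normal(size=100), index=expr.sample_ids)
        per_gene, counts, hist = interplay.gene_eigengene_crosscorrelation(
            expr, expr.gene_ids, target, alpha_levels=(0.01,)
        )
        frac = (counts.loc[0.01].sum()) / 400
        assert frac < 0.05  # ~1% expected under the null
        assert hist["count"].sum() == 400


class TestEigengeneCorrelation:
    def test_identity_and_negation(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=10)
        a = pd.Series(v, index=samples(10))
        r, p = interplay.eigengene_correlation(a, a)
        assert r == pytest.approx(1.0)
        r, _ = interplay.eigengene_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_constructed_orthogonality(self):
        n = 8  # alternating vs block-wise signs: exactly orthogonal
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        r, _ = interplay.eigengene_correlation(
            pd.Series(a, index=samples(n)), pd.Series(b, index=samples(n))
        )
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_rejected(self):
        a = pd.Series(np.ones(6), index=samples(6))
        b = pd.Series(np.arange(6, dtype=float), index=samples(6))
        with pytest.raises(ConstantFactorError):
            interplay.eigengene_correlation(a, b)
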