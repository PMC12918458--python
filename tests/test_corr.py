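import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nomoscan import corr


class TestDescribe:
    def test_symmetric_vector(self):
        d = corr.describe([1, 2, 3, 4, 5])
        assert d.mean == pytest.approx(3.0)
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.in_range

    def test_constant_vector_flagged(self):
        d = corr.describe([4.0] * 10)
        assert d.sd == 0.0
        assert d.undefined_moments
        assert np.isnan(d.skewness)

    def test_skewness_matches_adjusted_formula(self):
        # direct evaluation of the adjusted Fisher g1 on {0,0,0,1}
        x = np.array([0.0, 0.0, 0.0, 1.0])
        n = 4
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        g1 = m3 / m2 ** 1.5
        expected = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        d = corr.describe(x)
        assert d.skewness == pytest.approx(expected, rel=1e-12)
        assert d.skewness > 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            corr.describe([1.0, 2.0])


class TestCronbachAlpha:
    def test_three_items_half_correlated(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        cm = corr.CorrelationMatrix(["a", "b", "c"], m)
        assert corr.cronbach_alpha(cm) == pytest.approx(0.75)

    def test_two_items(self):
        m = np.array([[1.0, 0.6], [0.6, 1.0]])
        cm = corr.CorrelationMatrix(["a", "b"], m)
        assert corr.cronbach_alpha(cm) == pytest.approx(0.75)

    def test_uncorrelated_items(self):
        cm = corr.CorrelationMatrix(["a", "b", "c"], np.eye(3))
        assert corr.cronbach_alpha(cm) == pytest.approx(0.0)

    @pytest.mark.parametrize("k,r", [(3, 0.2), (5, 0.45), (10, 0.7)])
    def test_compound_symmetry_closed_form(self, k, r):
        m = np.full((k, k), r)
        np.fill_diagonal(m, 1.0)
        cm = corr.CorrelationMatrix([f"i{j}" for j in range(k)], m)
        assert corr.cronbach_alpha(cm) == pytest.approx(
            k * r / (1 + (k - 1) * r), rel=1e-14)

    def test_single_item_rejected(self):
        cm = corr.CorrelationMatrix(["a"], np.eye(1))
        with pytest.raises(ValueError):
            corr.cronbach_alpha(cm)


class TestPearsonMatrix:
    def test_self_correlation_is_one(self):
        data = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        cm = corr.pearson_matrix(data)
        assert cm.values[0, 0] == 1.0

    def test_perfect_negative(self):
        data = pd.DataFrame({"x": [1.0, 2, 3], "y": [3.0, 2, 1]})
        cm = corr.pearson_matrix(data)
        assert cm.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        data = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 3, 2, 4]})
        cm = corr.pearson_matrix(data)
        assert cm.values[0, 1] == pytest.approx(0.8)

    def test_listwise_deletion(self):
        data = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan],
                             "y": [1.0, 3, 2, 4, 100.0]})
        cm = corr.pearson_matrix(data, policy="listwise")
        assert cm.n == 4
        assert cm.values[0, 1] == pytest.approx(0.8)


class TestPolychoric:
    def test_independent_margins(self, rng):
        x = rng.integers(1, 4, size=20000)
        y = rng.integers(1, 5, size=20000)
        res = corr.polychoric_corr(x, y)
        assert abs(res.rho) < 0.02

    def test_monotone_2x2_hits_clip(self):
        x = np.array([1] * 50 + [2] * 50)
        res = corr.polychoric_corr(x, x.copy())
        assert res.rho == pytest.approx(corr.RHO_CLIP, abs=1e-6)

    def test_latent_normal_recovery(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=50000)
        cuts = [-0.6, 0.6]
        x = np.digitize(z[:, 0], cuts) + 1
        y = np.digitize(z[:, 1], cuts) + 1
        res = corr.polychoric_corr(x, y)
        assert res.rho == pytest.approx(0.5, abs=0.02)

    def test_thresholds_match_marginals(self, rng):
        from scipy.stats import norm
        x = rng.integers(1, 4, size=30000)
        y = rng.integers(1, 3, size=30000)
        res = corr.polychoric_corr(x, y)
        emp = norm.ppf(np.cumsum(np.bincount(x)[1:]) / x.size)[:-1]
        assert np.allclose(res.tau_x, emp, atol=1e-10)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            corr.polychoric_corr([1, 1, 1, 1], [1, 2, 1, 2], name_x="flat")


class TestFisherZ:
    def test_zero(self):
        assert corr.fisher_z(0.0) == 0.0

    def test_half(self):
        assert corr.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_roundtrip(self):
        assert corr.fisher_z_inv(corr.fisher_z(0.87)) == pytest.approx(
            0.87, abs=1e-12)

    @given(st.floats(min_value=-0.9999, max_value=0.9999))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_property(self, r):
        assert corr.fisher_z_inv(corr.fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            corr.fisher_z(1.0)


class TestStandardizedOLS:
    def _matrix(self, rxx, rxy, labels):
        k = len(labels)
        m = np.eye(k + 1)
        m[:k, :k] = rxx
        m[:k, k] = m[k, :k] = rxy
        return corr.CorrelationMatrix(labels + ["y"], m, n=100)

    def test_orthogonal_predictors(self):
        cm = self._matrix(np.eye(3), [0.3, 0.2, 0.1], ["a", "b", "c"])
        res = corr.standardized_ols(cm, "y", ["a", "b", "c"])
        assert res.betas == pytest.approx((0.3, 0.2, 0.1))
        assert res.r_squared == pytest.approx(0.14)

    def test_two_predictor_hand_example(self):
        rxx = np.array([[1.0, 0.5], [0.5, 1.0]])
        cm = self._matrix(rxx, [0.5, 0.4], ["a", "b"])
        res = corr.standardized_ols(cm, "y", ["a", "b"])
        assert res.betas == pytest.approx((0.4, 0.2), abs=1e-12)
        assert res.r_squared == pytest.approx(0.28, abs=1e-12)

    def test_null_correlations(self):
        cm = self._matrix(np.eye(3), [0.0, 0.0, 0.0], ["a", "b", "c"])
        res = corr.standardized_ols(cm, "y", ["a", "b", "c"])
        assert res.betas == pytest.approx((0, 0, 0), abs=1e-14)
        assert res.r_squared == 0.0

    def test_agrees_with_raw_least_squares(self, rng):
        n = 400
        x = rng.standard_normal((n, 3))
        y = x @ [0.5, -0.3, 0.2] + rng.standard_normal(n)
        data = pd.DataFrame(np.column_stack([x, y]),
                            columns=["a", "b", "c", "y"])
        cm = corr.pearson_matrix(data)
        res = corr.standardized_ols(cm, "y", ["a", "b", "c"])
        zs = (data - data.mean()) / data.std(ddof=1)
        beta_raw, *_ = np.linalg.lstsq(zs[["a", "b", "c"]], zs["y"], rcond=None)
        assert np.allclose(res.betas, beta_raw, atol=1e-8)

    def test_singular_block_rejected(self):
        m = np.array([[1.0, 1.0, 0.3], [1.0, 1.0, 0.3], [0.3, 0.3, 1.0]])
        cm = corr.CorrelationMatrix(["a", "b", "y"], m, n=50)
        with pytest.raises(ValueError, match="singular"):
            corr.standardized_ols(cm, "y", ["a", "b"])


class TestSmoothing:
    def test_indefinite_matrix_becomes_psd(self):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(m).min() < 0
        sm = corr.smooth_to_psd(m)
        assert np.linalg.eigvalsh(sm).min() >= -1e-12
        assert np.allclose(np.diag(sm), 1.0)

    def test_psd_input_untouched(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert np.allclose(corr.smooth_to_psd(m), m)
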