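import numpy as np
import pytest

from nomoscan import corr, mtmm


@pytest.fixture
def tiny_spec():
    """Two factors, three items each."""
    factors = ["f1", "f2"]
    assignment = {f"a{i}": "f1" for i in range(3)}
    assignment.update({f"b{i}": "f2" for i in range(3)})
    return mtmm.CFAModelSpec(factors=factors, assignment=assignment)


class TestCFAModelSpec:
    def test_df_arithmetic_default_design(self, cfa_spec):
        # 39 items -> 741 distinct correlations; 39 + 15 free parameters
        assert cfa_spec.n_items == 39
        assert cfa_spec.n_free == 54
        assert cfa_spec.df == 687

    def test_constraint_raises_df(self, cfa_spec):
        constrained = mtmm.CFAModelSpec(
            factors=cfa_spec.factors,
            assignment=dict(cfa_spec.assignment),
            fixed_corr={("SD3_mach", "DD_mach"): 1.0},
        )
        assert constrained.df == cfa_spec.df + 1

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            mtmm.CFAModelSpec(factors=["f1"], assignment={"x": "nope"})


class TestModelImpliedCorr:
    def test_zero_loadings_identity(self, tiny_spec):
        out = mtmm.model_implied_corr(np.zeros(6), np.eye(2), tiny_spec)
        assert np.allclose(out.values, np.eye(6))

    def test_same_factor_product(self, tiny_spec):
        lam = np.array([0.8, 0.8, 0.0, 0.0, 0.0, 0.0])
        out = mtmm.model_implied_corr(lam, np.eye(2), tiny_spec)
        assert out.values[0, 1] == pytest.approx(0.64)

    def test_cross_factor_scaled_by_phi(self, tiny_spec):
        lam = np.array([0.8, 0.0, 0.0, 0.5, 0.0, 0.0])
        phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = mtmm.model_implied_corr(lam, phi, tiny_spec)
        i, j = out.index("a0"), out.index("b0")
        assert out.values[i, j] == pytest.approx(0.20)


class TestFitDWLS:
    def test_zero_residual_fixed_point(self, tiny_spec):
        lam = np.array([0.7, 0.6, 0.8, 0.5, 0.65, 0.75])
        phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        implied = mtmm.model_implied_corr(lam, phi, tiny_spec)
        fit = mtmm.fit_dwls(implied, tiny_spec, n=500)
        assert fit.f_min < 1e-8
        assert np.allclose(fit.loadings, lam, atol=1e-4)
        assert fit.factor_corr[0, 1] == pytest.approx(0.4, abs=1e-4)

    def test_zero_residual_fixed_point_full_design(self, default_spec, cfa_spec):
        implied = mtmm.model_implied_corr(default_spec.loadings,
                                          default_spec.factor_corr, cfa_spec)
        fit = mtmm.fit_dwls(implied, cfa_spec, n=504)
        assert fit.f_min < 1e-8
        assert np.max(np.abs(fit.loadings - default_spec.loadings)) < 1e-4
        assert np.max(np.abs(fit.factor_corr - default_spec.factor_corr)) < 1e-4

    def test_parameter_recovery(self, default_spec, recovery_fit):
        assert recovery_fit.converged
        assert np.max(np.abs(recovery_fit.loadings
                             - default_spec.loadings)) < 0.05
        assert np.max(np.abs(recovery_fit.factor_corr
                             - default_spec.factor_corr)) < 0.05

    def test_recovered_convergent_correlations(self, recovery_fit):
        for trait, r in zip(["mach", "nar", "psych"], (0.927, 0.718, 0.876)):
            est = recovery_fit.phi_of(f"SD3_{trait}", f"DD_{trait}")
            assert est == pytest.approx(r, abs=0.05)

    def test_constrained_fit_loses_fit_on_divergent_truth(self, tiny_spec):
        lam = np.array([0.7, 0.6, 0.8, 0.5, 0.65, 0.75])
        phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        implied = mtmm.model_implied_corr(lam, phi, tiny_spec)
        free = mtmm.fit_dwls(implied, tiny_spec, n=500)
        constrained_spec = mtmm.CFAModelSpec(
            factors=tiny_spec.factors,
            assignment=dict(tiny_spec.assignment),
            fixed_corr={("f1", "f2"): 1.0},
        )
        constrained = mtmm.fit_dwls(implied, constrained_spec, n=500)
        cmp_ = mtmm.compare_nested(free, constrained)
        assert cmp_.delta_df == 1
        assert cmp_.delta_chi2 > 0
        assert not cmp_.anomaly


class TestFitIndices:
    def _fit(self, t, df, n=101):
        spec = mtmm.CFAModelSpec(factors=["f"], assignment={"a": "f", "b": "f"})
        return mtmm.CFAFit(spec=spec, loadings=np.zeros(2),
                           factor_corr=np.eye(1), f_min=t / (n - 1),
                           chi_square=t, df=df, n=n, converged=True, srmr=0.01)

    def test_perfect_fit(self):
        fit = self._fit(100.0, 100)
        base = self._fit(600.0, 100)
        idx = mtmm.fit_indices(fit, base)
        assert idx.rmsea == 0.0
        assert idx.cfi == 1.0

    def test_cfi_arithmetic(self):
        fit = self._fit(150.0, 100)
        base = self._fit(600.0, 100)
        idx = mtmm.fit_indices(fit, base)
        assert idx.cfi == pytest.approx(0.9)

    def test_rmsea_arithmetic(self):
        fit = self._fit(200.0, 100, n=101)
        base = self._fit(2000.0, 100, n=101)
        idx = mtmm.fit_indices(fit, base)
        assert idx.rmsea == pytest.approx(0.1)


class TestAVE:
    def test_uniform_loadings(self):
        assert mtmm.compute_ave([0.8, 0.8, 0.8]) == pytest.approx(0.64)

    def test_mixed_loadings(self):
        assert mtmm.compute_ave([0.6, 0.8]) == pytest.approx(0.50)

    def test_zero_loadings(self):
        assert mtmm.compute_ave([0.0, 0.0]) == 0.0


class TestFornellLarcker:
    def test_low_ave_high_corr_fails(self):
        # sqrt(.302) = .5495 < .927 -> discriminant validity fails
        phi = np.array([[1.0, 0.927], [0.927, 1.0]])
        per_factor, _ = mtmm.fornell_larcker(
            {"a": 0.302, "b": 0.302}, phi, ["a", "b"])
        assert per_factor["a"] is False

    def test_high_ave_low_corr_passes(self):
        phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        per_factor, _ = mtmm.fornell_larcker(
            {"a": 0.81, "b": 0.81}, phi, ["a", "b"])
        assert per_factor["a"] is True
        assert per_factor["b"] is True

    def test_tie_fails(self):
        phi = np.array([[1.0, 0.9], [0.9, 1.0]])
        per_factor, _ = mtmm.fornell_larcker(
            {"a": 0.81, "b": 0.81}, phi, ["a", "b"])  # sqrt(.81) = .9 exactly
        assert per_factor["a"] is False


class TestHTMT:
    def _corr(self, between, within_a, within_b):
        labels = ["a0", "a1", "b0", "b1"]
        m = np.eye(4)
        m[0, 1] = m[1, 0] = within_a
        m[2, 3] = m[3, 2] = within_b
        for i in (0, 1):
            for j in (2, 3):
                m[i, j] = m[j, i] = between
        return corr.CorrelationMatrix(labels, m)

    ASSIGN = {"a0": "fa", "a1": "fa", "b0": "fb", "b1": "fb"}

    def test_uniform_case_both_rules(self):
        cm = self._corr(0.3, 0.6, 0.6)
        for rule in ("arithmetic", "geometric"):
            assert mtmm.htmt(cm, self.ASSIGN, ("fa", "fb"), rule) == \
                pytest.approx(0.5)

    def test_all_equal_gives_one(self):
        cm = self._corr(0.6, 0.6, 0.6)
        assert mtmm.htmt(cm, self.ASSIGN, ("fa", "fb")) == pytest.approx(1.0)

    def test_rules_diverge(self):
        cm = self._corr(0.3, 0.4, 0.9)
        arit = mtmm.htmt(cm, self.ASSIGN, ("fa", "fb"), "arithmetic")
        geom = mtmm.htmt(cm, self.ASSIGN, ("fa", "fb"), "geometric")
        assert arit == pytest.approx(0.3 / 0.65, abs=1e-12)  # 0.4615
        assert geom == pytest.approx(0.5, abs=1e-12)

    def test_item_permutation_invariance(self, rng):
        labels = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        m = corr.smooth_to_psd(
            np.clip(rng.uniform(0.2, 0.7, (6, 6)), None, 0.95))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        assign = {l: ("fa" if l.startswith("a") else "fb") for l in labels}
        cm = corr.CorrelationMatrix(labels, m)
        base = mtmm.htmt(cm, assign, ("fa", "fb"))
        perm = [2, 0, 1, 5, 3, 4]
        cm2 = corr.CorrelationMatrix([labels[i] for i in perm],
                                     m[np.ix_(perm, perm)])
        assert mtmm.htmt(cm2, assign, ("fa", "fb")) == pytest.approx(base)

    def test_nonpositive_denominator_flagged(self):
        cm = self._corr(0.3, -0.5, -0.5)
        assert np.isnan(mtmm.htmt(cm, self.ASSIGN, ("fa", "fb")))


class TestCompareNested:
    def _fit(self, t, df):
        spec = mtmm.CFAModelSpec(factors=["f"], assignment={"a": "f"})
        return mtmm.CFAFit(spec=spec, loadings=np.zeros(1),
                           factor_corr=np.eye(1), f_min=0.0, chi_square=t,
                           df=df, n=504, converged=True, srmr=0.0)

    def test_identical_fits(self):
        res = mtmm.compare_nested(self._fit(100.0, 10), self._fit(100.0, 11))
        assert res.delta_chi2 == 0.0
        assert res.p_value == 1.0

    def test_constrained_overlap_statistic(self):
        # free T = 1801.18 (687 df); constrained adds 13.42 on one df
        res = mtmm.compare_nested(self._fit(1801.18, 687),
                                  self._fit(1814.60, 688))
        assert res.delta_chi2 == pytest.approx(13.42, abs=1e-9)
        assert res.delta_df == 1
        assert res.p_value < 0.001

    def test_large_difference(self):
        res = mtmm.compare_nested(self._fit(1801.18, 687),
                                  self._fit(1801.18 + 73.23, 688))
        assert res.p_value < 0.001

    def test_non_monotone_flagged(self):
        res = mtmm.compare_nested(self._fit(100.0, 10), self._fit(90.0, 11))
        assert res.anomaly

    def test_bad_nesting_rejected(self):
        with pytest.raises(ValueError):
            mtmm.compare_nested(self._fit(100.0, 11), self._fit(100.0, 10))
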