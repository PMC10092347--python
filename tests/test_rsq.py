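"""Tests of the R-squared measures and their algebraic identities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import statsmodels.api as sm

import surrogate_rsq as sr


class TestOlsR2:
    def test_exact_linear_response_gives_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = 2.0 + X @ [1.0, -2.0, 0.5]
        assert sr.ols_r2(y, X) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        assert sr.ols_r2(rng.normal(size=5000), rng.normal(size=(5000, 2))) < 0.01

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = X @ [0.5, 1.0, -0.3] + rng.normal(size=20)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        sse = float((yc - Xc @ beta) @ (yc - Xc @ beta))
        expected = 1.0 - sse / float(yc @ yc)
        assert sr.ols_r2(y, X) == pytest.approx(expected, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="rank deficient.*c"):
            sr.ols_r2(rng.normal(size=30), X, var_names=["a", "b", "c"])

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sr.ols_r2(np.ones(10), np.arange(10.0))

    def test_empty_design_returns_zero(self):
        assert sr.ols_r2(np.arange(5.0), np.empty((5, 0))) == 0.0


class TestSurrogateR2:
    def test_empty_subset_is_zero(self, setting1_fit, setting1_data):
        data, _ = setting1_data
        assert sr.surrogate_r2(setting1_fit, data, subset=[], M=2, seed=0).value == 0.0

    def test_full_subset_equals_direct_ols(self, setting1_data):
        data, _ = setting1_data
        params = sr.setting1_design().params
        res = sr.surrogate_r2(params, data, M=1, seed=4)
        s = sr.generate_surrogate(params, data, seed=4).s
        assert res.value == pytest.approx(sr.ols_r2(s, data.X), abs=1e-14)

    def test_subset_outside_full_model_rejected(self, setting1_data):
        data, _ = setting1_data
        reduced_fit = sr.fit_probit(data, ["X1", "X2"])
        with pytest.raises(ValueError, match="must reuse the full-model surrogate"):
            sr.surrogate_r2(reduced_fit, data, subset=["X3"], M=1, seed=0)

    def test_average_is_mean_of_draw_values(self, setting1_fit, setting1_data):
        data, _ = setting1_data
        res = sr.surrogate_r2(setting1_fit, data, M=8, seed=5)
        assert res.M == 8 and res.draw_values.shape == (8,)
        assert res.value == pytest.approx(res.draw_values.mean(), abs=1e-14)

    def test_monotone_over_all_subsets_per_draw(self):
        """Common-surrogate R2 is exactly non-decreasing along nested models,
        for every draw, over the whole 4-covariate subset lattice."""
        data, _ = sr.gen_setting3(400, seed=8)
        fit = sr.fit_probit(data)
        common = sr.CommonSurrogate(fit, data, M=3, seed=13)
        names = data.var_names
        values = {}
        for k in range(5):
            for sub in itertools.combinations(names, k):
                values[frozenset(sub)] = (common.r2(sub).draw_values
                                          if sub else np.zeros(3))
        for a, va in values.items():
            for b, vb in values.items():
                if a < b:
                    assert np.all(va <= vb + 1e-12)


class TestMzMcfadden:
    def test_zero_slopes_give_zero_mz(self, setting1_data):
        data, _ = setting1_data
        fit = sr.fit_probit(data, [])
        assert sr.mz_r2(fit, data).value == 0.0

    def test_null_fit_gives_zero_mcfadden(self, setting1_data):
        data, _ = setting1_data
        fit = sr.fit_probit(data, [])
        assert sr.mcfadden_r2(fit).value == pytest.approx(0.0, abs=1e-12)

    def test_both_strictly_below_one(self, setting1_fit, setting1_data):
        data, _ = setting1_data
        assert 0 < sr.mz_r2(setting1_fit, data).value < 1
        assert 0 < sr.mcfadden_r2(setting1_fit).value < 1


class TestAsymptoticSurrogate:
    def test_full_subset_identity_with_mz(self, setting1_fit, setting1_data):
        data, _ = setting1_data
        asym = sr.asymptotic_surrogate_r2(setting1_fit, data)
        assert asym.value == pytest.approx(sr.mz_r2(setting1_fit, data).value, abs=1e-12)

    def test_empty_subset_zero(self, setting1_fit, setting1_data):
        data, _ = setting1_data
        assert sr.asymptotic_surrogate_r2(setting1_fit, data, subset=[]).value == 0.0

    def test_large_n_agreement_with_surrogate(self):
        data, _ = sr.gen_example1(50_000, seed=31)
        fit = sr.fit_probit(data)
        asym = sr.asymptotic_surrogate_r2(fit, data, subset=["X1"]).value
        surr = sr.surrogate_r2(fit, data, subset=["X1"], M=10, seed=31).value
        assert asym == pytest.approx(surr, abs=0.02)


class TestFCorrespondence:
    def test_f_zero_maps_to_zero(self):
        assert sr.r2_from_f(0.0, 3, 100) == 0.0
        assert sr.f_from_r2(1.0, 3, 100) == np.inf

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.0, 0.999), st.integers(1, 10), st.integers(20, 500))
    def test_round_trip_identity(self, r2, p, n):
        assert sr.r2_from_f(sr.f_from_r2(r2, p, n), p, n) == pytest.approx(r2, abs=1e-12)

    def test_anova_f_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, 0.5, 0.0] + rng.normal(size=40)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert sr.f_from_r2(sr.ols_r2(y, X), 3, 40) == pytest.approx(ols.fvalue, rel=1e-10)

    def test_correlation_identity_prop3(self, setting1_data):
        """Single-draw surrogate R2 equals corr(s, fitted s)^2."""
        data, _ = setting1_data
        fit = sr.fit_probit(data)
        s = sr.generate_surrogate(fit, data, seed=2).s
        r2 = sr.ols_r2(s, data.X)
        Xc = np.column_stack([np.ones(data.n), data.X])
        shat = Xc @ np.linalg.lstsq(Xc, s, rcond=None)[0]
        assert r2 == pytest.approx(np.corrcoef(s, shat)[0, 1] ** 2, abs=1e-10)


class TestPopulationLimit:
    def test_zero_beta(self):
        assert sr.population_limit_r2(np.zeros(3), np.eye(3)) == 0.0

    def test_setting1_direct_arithmetic(self):
        # b'Sb = .8 sum(b^2) + .2 (sum b)^2 with equicorrelated unit-variance S
        d = sr.setting1_design()
        b = d.params.beta
        quad = 0.8 * np.sum(b**2) + 0.2 * np.sum(b) ** 2
        assert quad == pytest.approx(3.728, abs=1e-12)
        assert d.limit_r2() == pytest.approx(quad / (quad + 1.0), abs=1e-12)
        assert d.limit_r2() == pytest.approx(0.7885, abs=5e-4)

    def test_setting1_reduced_model_limits(self):
        # published limiting values .671 (without X1) and .565 (without X1, X2)
        d = sr.setting1_design()
        names = list(d.var_names)
        assert d.limit_r2(names[1:]) == pytest.approx(0.671, abs=2e-3)
        assert d.limit_r2(names[2:]) == pytest.approx(0.565, abs=2e-3)

    def test_non_pd_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            sr.population_limit_r2(np.ones(2), np.ones((2, 2)))


class TestDistributionalEquality:
    def test_surrogate_and_latent_r2_same_distribution(self):
        """On a fixed design, the true-parameter surrogate R2 and the latent
        OLS R2 are draws from one distribution (two-sample KS)."""
        from scipy.stats import ks_2samp

        d = sr.setting1_design()
        data, _ = sr.gen_setting1(2000, seed=77)
        X = data.X
        mu = X @ d.params.beta
        rng = np.random.default_rng(55)
        r2_latent = np.empty(300)
        r2_surr = np.empty(300)
        for r in range(300):
            z = mu + rng.standard_normal(2000)
            r2_latent[r] = sr.ols_r2(z, X)
            y = 1 + np.searchsorted(d.params.alpha, z)
            dd = sr.OrdinalDataset.from_arrays(X, y, var_names=d.var_names, J=3)
            s = sr.generate_surrogate(d.params, dd, seed=(55, r)).s
            r2_surr[r] = sr.ols_r2(s, X)
        assert ks_2samp(r2_latent, r2_surr).pvalue > 0.01
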