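"""Unit tests for the cumulative-probit container and ML fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr
from scipy.stats import norm
from statsmodels.discrete.discrete_model import Probit
from statsmodels.miscmodels.ordinal_model import OrderedModel

import surrogate_rsq as sr
from surrogate_rsq.probit import null_log_likelihood


class TestOrdinalDataset:
    def test_binary_01_normalized_to_12(self):
        X = np.zeros((4, 1))
        d = sr.OrdinalDataset.from_arrays(X, [0, 1, 0, 1], var_names=["x"])
        assert set(d.y.tolist()) == {1, 2} and d.J == 2

    @pytest.mark.parametrize("y,err", [
        ([1, 1, 1, 1], "single observed category"),
        ([1, 3, 1, 3], "unobserved response categories"),
        ([1.5, 2, 1, 2], "integers"),
    ])
    def test_invalid_responses_rejected(self, y, err):
        with pytest.raises(ValueError, match=err):
            sr.OrdinalDataset.from_arrays(np.zeros((4, 1)), y, var_names=["x"])

    def test_column_lookup_by_name(self, toy_dataset):
        assert toy_dataset.columns(["v"]).tolist() == [1]
        with pytest.raises(KeyError, match="unknown covariate"):
            toy_dataset.columns(["w"])


class TestFitProbit:
    def test_matches_statsmodels_ordinal_mle(self, setting1_data):
        data, _ = setting1_data
        fit = sr.fit_probit(data)
        oracle = OrderedModel(data.y, data.X, distr="probit").fit(method="bfgs", disp=False)
        assert fit.converged
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-5)
        np.testing.assert_allclose(fit.params.beta, oracle.params[: data.p], atol=2e-4)
        np.testing.assert_allclose(fit.beta_se, oracle.bse[: data.p], rtol=1e-3)

    def test_binary_reduces_to_ordinary_probit(self, binary_data):
        data, _ = binary_data
        fit = sr.fit_probit(data)
        # statsmodels Probit models Pr(Y=2) = Phi(c + x'b); our form has
        # Pr(Y=2) = Phi(x'beta - alpha_1), so c = -alpha_1 and b = beta
        exog = np.column_stack([np.ones(data.n), data.X])
        oracle = Probit(data.y - 1, exog).fit(disp=False)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)
        assert -fit.params.alpha[0] == pytest.approx(oracle.params[0], abs=1e-5)
        np.testing.assert_allclose(fit.params.beta, oracle.params[1:], atol=1e-5)

    def test_null_design_slopes_within_3_se(self):
        rng = np.random.default_rng(0)
        n = 5000
        X = rng.standard_normal((n, 3))
        y = 1 + (rng.standard_normal(n) > 0.4)
        data = sr.OrdinalDataset.from_arrays(X, y)
        fit = sr.fit_probit(data)
        assert np.all(np.abs(fit.params.beta) < 3 * fit.beta_se)

    def test_example1_parameter_recovery_large_n(self):
        # design truth: latent 2 - X1 + .7 X2, i.e. alpha=-2, beta=(-1, .7)
        data, _ = sr.gen_example1(50_000, seed=123)
        fit = sr.fit_probit(data)
        assert fit.params.alpha[0] == pytest.approx(-2.0, abs=0.06)
        assert fit.params.beta[0] == pytest.approx(-1.0, abs=0.05)
        assert fit.params.beta[1] == pytest.approx(0.7, abs=0.05)

    def test_null_model_closed_form(self, setting1_data):
        data, _ = setting1_data
        fit = sr.fit_probit(data, [])
        freq = np.bincount(data.y - 1)
        expected = np.sum(freq * np.log(freq / data.n))
        assert fit.loglik == pytest.approx(expected, abs=1e-10)
        assert fit.loglik == pytest.approx(fit.null_loglik, abs=1e-10)
        # cutpoints reproduce the observed cumulative frequencies
        np.testing.assert_allclose(ndtr(fit.params.alpha), np.cumsum(freq)[:-1] / data.n)

    def test_nested_loglik_monotone(self, setting1_data, setting1_fit):
        data, _ = setting1_data
        prev = sr.fit_probit(data, []).loglik
        for k in (2, 5, 8, 10):
            ll = sr.fit_probit(data, list(data.var_names[:k])).loglik
            assert ll >= prev - 1e-6
            prev = ll
        assert setting1_fit.loglik >= prev - 1e-6
        assert setting1_fit.loglik >= setting1_fit.null_loglik - 1e-6

    def test_complete_separation_raises(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(int) + 1
        data = sr.OrdinalDataset.from_arrays(x[:, None], y, var_names=["x"])
        with pytest.raises(sr.SeparationError, match="separated"):
            sr.fit_probit(data)

    def test_too_small_sample_rejected(self):
        data = sr.OrdinalDataset.from_arrays(np.eye(3), [1, 2, 2], var_names=list("abc"))
        with pytest.raises(ValueError, match="too small"):
            sr.fit_probit(data)


class TestCumulativeProbs:
    def test_symmetric_binary_is_half(self):
        p = sr.ProbitParams(alpha=[0.0], beta=[0.0, 0.0])
        out = sr.cumulative_probs(p, np.random.default_rng(1).normal(size=(5, 2)))
        np.testing.assert_allclose(out, 0.5)

    def test_standard_normal_cdf_oracle(self):
        p = sr.ProbitParams(alpha=[1.0, 2.9], beta=[0.0])
        out = sr.cumulative_probs(p, [[0.0]])
        np.testing.assert_allclose(out[0, 0], norm.cdf(1.0), atol=1e-12)
        np.testing.assert_allclose(out[0, 1], norm.cdf(2.9) - norm.cdf(1.0), atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one_random_params(self, J, seed):
        rng = np.random.default_rng(seed)
        alpha = np.sort(rng.normal(scale=2, size=J - 1))
        alpha += np.arange(J - 1) * 1e-3  # break ties
        p = sr.ProbitParams(alpha=alpha, beta=rng.normal(size=3))
        out = sr.cumulative_probs(p, rng.normal(size=(20, 3)) * 3)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(out >= 0)

    def test_dimension_mismatch(self):
        p = sr.ProbitParams(alpha=[0.0], beta=[1.0])
        with pytest.raises(ValueError, match="columns"):
            sr.cumulative_probs(p, np.zeros((3, 2)))


class TestLogLikelihood:
    def test_certain_category_gives_zero(self):
        p = sr.ProbitParams(alpha=[-40.0], beta=[0.0])
        d = sr.OrdinalDataset.from_arrays(np.zeros((2, 1)), [1, 2], var_names=["x"], J=2)
        # category 2 has probability ~1; restrict to those rows via weights:
        probs = sr.cumulative_probs(p, d.X)
        assert np.log(probs[1, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_product_oracle(self, toy_dataset):
        p = sr.ProbitParams(alpha=[-0.2, 1.1], beta=[0.6, -0.4])
        probs = sr.cumulative_probs(p, toy_dataset.X)
        expected = float(np.sum(np.log(probs[np.arange(10), toy_dataset.y - 1])))
        assert sr.log_likelihood(p, toy_dataset) == pytest.approx(expected, abs=1e-10)

    def test_multinomial_closed_form_for_null(self, setting1_data):
        data, _ = setting1_data
        freq = np.bincount(data.y - 1)
        assert null_log_likelihood(data.y) == pytest.approx(
            float(np.sum(freq * np.log(freq / data.n))), abs=1e-10)

    def test_extreme_params_finite(self, toy_dataset):
        p = sr.ProbitParams(alpha=[-50.0, -49.0], beta=[30.0, -30.0])
        ll = sr.log_likelihood(p, toy_dataset)
        assert np.isfinite(ll) and ll < 0
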