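"""Model-core tests: containers, likelihood, priors, gradients."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import cauchy, norm

import hierlogit as hl
from hierlogit.errors import InvalidArgumentError

from conftest import random_instance


class TestInverseLogit:
    @pytest.mark.parametrize("eta,expected", [
        (0.0, 0.5),
        (np.log(3.0), 0.75),
        (-np.log(3.0), 0.25),
    ])
    def test_known_values(self, eta, expected):
        assert hl.inverse_logit(eta) == pytest.approx(expected, rel=1e-12)

    def test_extreme_tails_stay_in_open_interval(self):
        low = hl.inverse_logit(-50.0)
        assert 0.0 < low < 1e-20
        # no overflow anywhere up to +-700
        assert hl.inverse_logit(700.0) <= 1.0
        assert hl.inverse_logit(-700.0) >= 0.0

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidArgumentError):
            hl.inverse_logit(np.nan)
        with pytest.raises(InvalidArgumentError):
            hl.inverse_logit(np.inf)


class TestDataset:
    def test_rejects_bad_outcome_group_and_names(self):
        good = dict(y=[0, 1, 1], X=[[1.0], [0.0], [2.0]], group=[1, 2, 3],
                    covariate_names=("x",), group_labels=("a", "b", "c"))
        hl.Dataset(**good)  # sanity: the base case is valid
        with pytest.raises(InvalidArgumentError):
            hl.Dataset(**{**good, "y": [0, 2, 1]})
        with pytest.raises(InvalidArgumentError):
            hl.Dataset(**{**good, "group": [1, 3, 3]})  # group 2 empty
        with pytest.raises(InvalidArgumentError):
            hl.Dataset(**{**good, "X": [[1.0], [np.nan], [2.0]]})
        with pytest.raises(InvalidArgumentError):
            hl.Dataset(**{**good, "covariate_names": ("x", "x")})

    def test_csv_round_trip(self, tmp_path, small_dataset):
        data, _ = small_dataset
        path = tmp_path / "survey.csv"
        data.to_frame().to_csv(path, index=False)
        back = hl.Dataset.from_csv(path, outcome="intend_quit", group="grade")
        np.testing.assert_array_equal(back.y, data.y)
        np.testing.assert_allclose(back.X, data.X)
        np.testing.assert_array_equal(back.group, data.group)
        assert back.covariate_names == data.covariate_names

    def test_missing_values_rejected_at_load(self, tmp_path):
        frame = pd.DataFrame({"yq": [0, 1, None], "grade": [1, 2, 3], "x": [1.0, 2.0, 3.0]})
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(InvalidArgumentError, match="missing"):
            hl.Dataset.from_csv(path, outcome="yq", group="grade")


def test_prior_spec_rejects_non_positive_scales():
    for kwargs in ({"beta_scale": 0.0}, {"alpha_scale": -1.0}, {"sigma_scale": 0.0}):
        with pytest.raises(InvalidArgumentError):
            hl.PriorSpec(**kwargs)


def test_param_vector_packing_round_trip():
    pv = hl.ParamVector(alpha0=0.5, mu_raw=[0.1, -0.2, 0.3], log_sigma_mu=-1.0,
                        beta=[1.0, 2.0])
    assert pv.dim == 1 + 3 + 1 + 2
    back = hl.ParamVector.from_array(pv.to_array(), n_groups=3)
    assert back.alpha0 == pv.alpha0 and back.log_sigma_mu == pv.log_sigma_mu
    np.testing.assert_array_equal(back.beta, pv.beta)
    assert pv.sigma_mu == pytest.approx(np.exp(-1.0))
    with pytest.raises(InvalidArgumentError):
        hl.ParamVector(alpha0=np.nan, mu_raw=[0.0], log_sigma_mu=0.0, beta=[0.0])


class TestLinearPredictor:
    def test_zero_params_give_zero_logits(self):
        data, _, _ = random_instance(0)
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=np.zeros(data.n_covariates))
        np.testing.assert_array_equal(hl.linear_predictor(params, data), np.zeros(data.n))

    def test_simple_arithmetic(self):
        data = hl.Dataset(y=[1, 0, 1], X=[[3.0], [3.0], [3.0]], group=[1, 2, 3],
                          covariate_names=("x",), group_labels=("a", "b", "c"))
        params = hl.ParamVector(alpha0=1.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=[2.0])
        np.testing.assert_allclose(hl.linear_predictor(params, data), [7.0, 7.0, 7.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_row_loop(self, seed):
        data, params, _ = random_instance(seed)
        eta = hl.linear_predictor(params, data)
        sigma = params.sigma_mu
        for i in range(data.n):
            expected = (params.alpha0 + sigma * params.mu_raw[data.group[i] - 1]
                        + float(data.X[i] @ params.beta))
            assert eta[i] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        data, params, _ = random_instance(1)
        bad = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                             beta=np.zeros(data.n_covariates + 1))
        with pytest.raises(InvalidArgumentError):
            hl.linear_predictor(bad, data)


class TestLogLikelihood:
    def test_single_row_at_even_odds(self):
        data = hl.Dataset(y=[1, 1, 1], X=[[0.0]] * 3, group=[1, 2, 3],
                          covariate_names=("x",), group_labels=("a", "b", "c"))
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=[0.0])
        assert hl.log_likelihood(params, data) == pytest.approx(3 * np.log(0.5))

    def test_two_rows_at_three_to_one_odds(self):
        # both rows get logit ln 3 => pi = 0.75; y = (1, 0, 1) over three groups
        data = hl.Dataset(y=[1, 0, 1], X=[[1.0], [1.0], [1.0]], group=[1, 2, 3],
                          covariate_names=("x",), group_labels=("a", "b", "c"))
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=[np.log(3.0)])
        expected = np.log(0.75) + np.log(0.25) + np.log(0.75)
        assert hl.log_likelihood(params, data) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_product_then_log_oracle(self, seed):
        data, params, _ = random_instance(seed, n_max=20)
        pi = hl.inverse_logit(hl.linear_predictor(params, data))
        oracle = float(np.log(np.prod(pi ** data.y * (1 - pi) ** (1 - data.y))))
        assert hl.log_likelihood(params, data) == pytest.approx(oracle, rel=1e-10)

    def test_row_permutation_invariance(self):
        data, params, _ = random_instance(3)
        perm = np.random.default_rng(0).permutation(data.n)
        shuffled = hl.Dataset(y=data.y[perm], X=data.X[perm], group=data.group[perm],
                              covariate_names=data.covariate_names,
                              group_labels=data.group_labels)
        assert hl.log_likelihood(params, shuffled) == pytest.approx(
            hl.log_likelihood(params, data), rel=1e-12)

    def test_finite_for_huge_logits(self):
        data = hl.Dataset(y=[1, 0, 1], X=[[500.0], [500.0], [500.0]], group=[1, 2, 3],
                          covariate_names=("x",), group_labels=("a", "b", "c"))
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=[1.0])
        assert np.isfinite(hl.log_likelihood(params, data))


class TestLogPrior:
    def test_closed_form_at_zero_params(self):
        priors = hl.PriorSpec(beta_scale=10.0, alpha_scale=10.0, sigma_scale=2.5)
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=np.zeros(2))
        # independent closed-form sum: normals at 0, half-Cauchy at sigma = 1,
        # Jacobian log sigma = 0
        expected = (norm.logpdf(0.0, scale=10.0) * 3       # alpha0 + 2 betas
                    + norm.logpdf(0.0, scale=1.0) * 3       # mu_raw
                    + np.log(2.0) + cauchy.logpdf(1.0, scale=2.5))
        assert hl.log_prior(params, priors) == pytest.approx(expected, rel=1e-12)

    def test_decreasing_in_coefficient_magnitude(self):
        priors = hl.PriorSpec()
        values = []
        for b in (0.0, 1.0, 5.0, 20.0):
            params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                    beta=[b])
            values.append(hl.log_prior(params, priors))
        assert values == sorted(values, reverse=True)

    def test_sigma_scale_change_touches_only_scale_terms(self):
        params = hl.ParamVector(alpha0=0.7, mu_raw=[0.1, -0.4, 0.2],
                                log_sigma_mu=0.3, beta=[1.0, -2.0])
        base = hl.PriorSpec(sigma_scale=2.5)
        doubled = hl.PriorSpec(sigma_scale=5.0)
        sigma = params.sigma_mu
        delta = hl.log_prior(params, doubled) - hl.log_prior(params, base)
        expected_delta = ((np.log(2.0) + cauchy.logpdf(sigma, scale=5.0))
                          - (np.log(2.0) + cauchy.logpdf(sigma, scale=2.5)))
        assert delta == pytest.approx(expected_delta, rel=1e-12)


class TestLogPosterior:
    @pytest.mark.parametrize("seed", range(4))
    def test_is_sum_of_components(self, seed):
        data, params, priors = random_instance(seed)
        assert hl.log_posterior(params, data, priors) == pytest.approx(
            hl.log_likelihood(params, data) + hl.log_prior(params, priors), rel=1e-12)

    def test_all_ones_outcome_has_finite_interior_maximizer(self):
        # with all y = 1 the likelihood keeps rising in alpha0 but the prior
        # dominates eventually: a 1-d scan must peak strictly inside the range
        data = hl.Dataset(y=np.ones(12), X=np.zeros((12, 1)),
                          group=np.tile([1, 2, 3], 4),
                          covariate_names=("x",), group_labels=("a", "b", "c"))
        priors = hl.PriorSpec()
        grid = np.linspace(-5, 60, 400)
        vals = [hl.log_posterior(
            hl.ParamVector(alpha0=a, mu_raw=np.zeros(3), log_sigma_mu=0.0, beta=[0.0]),
            data, priors) for a in grid]
        peak = int(np.argmax(vals))
        assert 0 < peak < len(grid) - 1

    def test_group_relabeling_invariance(self):
        data, params, priors = random_instance(5)
        perm = np.array([2, 0, 1])  # relabel groups 1,2,3 -> 3,1,2
        relabeled = hl.Dataset(
            y=data.y, X=data.X, group=perm[data.group - 1] + 1,
            covariate_names=data.covariate_names, group_labels=data.group_labels)
        inv = np.argsort(perm)
        params_re = hl.ParamVector(alpha0=params.alpha0, mu_raw=params.mu_raw[inv],
                                   log_sigma_mu=params.log_sigma_mu, beta=params.beta)
        assert hl.log_posterior(params_re, relabeled, priors) == pytest.approx(
            hl.log_posterior(params, data, priors), rel=1e-12)


class TestGradient:
    def test_matches_finite_differences_on_many_instances(self):
        """Analytic gradient vs central differences on 100 random small models."""
        worst = 0.0
        for seed in range(100):
            data, params, priors = random_instance(seed)
            grad = hl.grad_log_posterior(params, data, priors)
            theta = params.to_array()
            for i in range(theta.size):
                step = np.zeros_like(theta)
                step[i] = 1e-5
                hi = hl.log_posterior(hl.ParamVector.from_array(theta + step, 3), data, priors)
                lo = hl.log_posterior(hl.ParamVector.from_array(theta - step, 3), data, priors)
                fd = (hi - lo) / 2e-5
                worst = max(worst, abs(grad[i] - fd) / max(1.0, abs(fd)))
        assert worst < 1e-5

    def test_beta_gradient_closed_form_at_prior_mode(self):
        data, _, _ = random_instance(11)
        priors = hl.PriorSpec()
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=np.zeros(data.n_covariates))
        grad = hl.grad_log_posterior(params, data, priors)
        expected_beta = data.X.T @ (data.y - 0.5)
        np.testing.assert_allclose(grad[5:], expected_beta, rtol=1e-12)

    def test_prior_score_at_one_prior_sd(self):
        # likelihood-free check: with a single all-zero covariate the data term
        # vanishes for beta, so the gradient at beta = scale is the normal score -1/scale
        data = hl.Dataset(y=[1, 0, 1], X=np.zeros((3, 1)), group=[1, 2, 3],
                          covariate_names=("x",), group_labels=("a", "b", "c"))
        priors = hl.PriorSpec(beta_scale=10.0)
        params = hl.ParamVector(alpha0=0.0, mu_raw=np.zeros(3), log_sigma_mu=0.0,
                                beta=[10.0])
        grad = hl.grad_log_posterior(params, data, priors)
        assert grad[-1] == pytest.approx(-1.0 / 10.0, rel=1e-12)
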