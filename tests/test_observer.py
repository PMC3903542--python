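"""Unit and property tests for the Bayesian observer model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from huemem import (
    BayesianObserver,
    InvalidParameterError,
    ObserverParams,
    StimulusPresentation,
    params_for_block,
    posterior_estimate,
    shrinkage_weight,
    simulate_response,
)

INF = float("inf")


class TestPosteriorEstimate:
    def test_uniform_prior_returns_signal(self):
        assert posterior_estimate(0.7, 0.1, prior_mean=9.9, prior_sigma=INF) == 0.7

    def test_uninformative_signal_returns_prior_mean(self):
        assert posterior_estimate(0.7, INF, prior_mean=0.3, prior_sigma=1.0) == 0.3

    def test_equal_widths_average(self):
        # closed form: w = 1/(1+1) = 0.5 -> 0.5 * 0.5 + 0.5 * 0 = 0.25
        assert posterior_estimate(0.5, 1.0, prior_mean=0.0, prior_sigma=1.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            posterior_estimate(0.5, bad, 0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            posterior_estimate(0.5, 1.0, 0.0, bad)

    @given(
        signal=st.floats(-10, 10),
        prior_mean=st.floats(-10, 10),
        lik=st.floats(0.01, 100),
        prior=st.floats(0.01, 100),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_conjugate_gaussian_closed_form_and_is_bounded(
        self, signal, prior_mean, lik, prior
    ):
        w = prior**2 / (prior**2 + lik**2)
        est = posterior_estimate(signal, lik, prior_mean, prior)
        assert est == pytest.approx(w * signal + (1 - w) * prior_mean, abs=1e-12)
        lo, hi = min(signal, prior_mean), max(signal, prior_mean)
        assert lo - 1e-12 <= est <= hi + 1e-12


class TestObserverParams:
    def test_defaults_valid(self):
        ObserverParams()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_sensory": 0.0},
            {"sigma_sensory": -0.1},
            {"kappa_memory": 0.5},
            {"lapse_rate": 0.5},
            {"lapse_rate": -0.01},
            {"prior_reflectance_sigma": 0.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ObserverParams(**kwargs)

    def test_infinite_priors_allowed(self):
        p = ObserverParams(prior_reflectance_sigma=INF, prior_illuminant_sigma=INF)
        assert math.isinf(p.prior_reflectance_sigma)

    def test_remembered_requires_first_interval(self):
        with pytest.raises(InvalidParameterError):
            StimulusPresentation(1.0, "gray", interval="second", remembered=True)

    def test_invalid_params_propagate_through_simulate(self):
        ref = StimulusPresentation(1.0, "gray")
        with pytest.raises(InvalidParameterError):
            simulate_response("not params", ref, ref, np.random.default_rng(0))


class TestSimulateResponse:
    def test_identical_stimuli_give_chance_performance(self):
        """Symmetric setup: P(test bluer) ~ 0.5 over many trials."""
        params = ObserverParams(lapse_rate=0.0, response_criterion=0.0)
        observer = BayesianObserver(params)
        rng = np.random.default_rng(1)
        stim = lambda: StimulusPresentation(3.2, "gray")
        n = 4000
        hits = sum(observer(stim(), stim(), rng) for _ in range(n))
        assert abs(hits / n - 0.5) < 3 * 0.5 / math.sqrt(n)

    def test_deterministic_ordering_without_noise(self):
        """Near-zero noise, uniform priors: bluer test is always chosen."""
        params = ObserverParams(
            sigma_sensory=1e-9,
            sigma_illuminant=1e-9,
            sigma_decision=0.0,
            lapse_rate=0.0,
            response_criterion=0.0,
            prior_reflectance_sigma=INF,
            prior_illuminant_sigma=INF,
        )
        rng = np.random.default_rng(2)
        ref = StimulusPresentation(3.2, "gray")
        assert simulate_response(params, ref, StimulusPresentation(3.21, "gray"), rng)
        assert not simulate_response(params, ref, StimulusPresentation(3.19, "gray"), rng)

    def test_probability_monotone_in_test_hue(self):
        """Empirical P(test bluer) is non-decreasing within binomial error."""
        params = ObserverParams()
        observer = BayesianObserver(params)
        rng = np.random.default_rng(3)
        levels = np.linspace(2.9, 3.5, 7)
        n = 2000
        ref = StimulusPresentation(3.2, "gray", interval="first", remembered=True)
        props = []
        for level in levels:
            test = StimulusPresentation(level, "gray")
            props.append(sum(observer(ref, test, rng) for _ in range(n)) / n)
        se = 3 * math.sqrt(0.25 / n) * math.sqrt(2)
        assert all(b - a > -se for a, b in zip(props, props[1:])), props


class TestClosedFormShrinkage:
    def test_remembered_pse_matches_shrinkage_law(self, pse_estimator):
        """Memory PSE obeys the conjugate-Gaussian shrinkage closed form.

        With a uniform illuminant prior and symmetric backgrounds, the
        model's PSE for a remembered reference r is
        mu + (w_mem / w_test) (r - mu) with w = s_p^2/(s_p^2 + s_lik^2)
        evaluated at the memory-widened and simultaneous likelihood widths.
        """
        params = ObserverParams(
            sigma_sensory=0.09,
            kappa_memory=2.0,
            prior_reflectance_mean=3.2,
            prior_reflectance_sigma=0.25,
            prior_illuminant_sigma=INF,
            sigma_decision=0.02,
            lapse_rate=0.0,
            response_criterion=0.0,
        )
        w_mem = shrinkage_weight(0.25, 0.18)
        w_test = shrinkage_weight(0.25, 0.09)
        for ref, seed in [(2.9, 10), (3.5, 11)]:
            expected = 3.2 + (w_mem / w_test) * (ref - 3.2)
            fit = pse_estimator(
                params,
                reference_hue=ref,
                delayed=True,
                levels=expected + np.linspace(-0.35, 0.35, 7),
                n_per_level=3000,
                seed=seed,
            )
            assert fit.location == pytest.approx(expected, abs=0.015)
            # extreme references are drawn toward the prior: memory bias
            # has a negative slope across references
            assert abs(fit.location - 3.2) < abs(ref - 3.2)

    def test_constancy_biases_opposite_and_comparable(self, pse_estimator):
        """Asymmetric backgrounds shift the match up (ref on gray) or down
        (ref on blue) by the inferred illuminant difference."""
        shift = 0.3
        params = ObserverParams(
            illuminant_shift_blue=shift,
            sigma_illuminant=0.01,  # strong illuminant likelihood
            prior_illuminant_sigma=INF,
            prior_reflectance_sigma=INF,
            lapse_rate=0.0,
            response_criterion=0.0,
        )
        fit_gray = pse_estimator(
            params, reference_hue=3.2, reference_background="gray",
            test_background="blue", levels=3.2 + shift + np.linspace(-0.3, 0.3, 7),
            n_per_level=2000, seed=20,
        )
        fit_blue = pse_estimator(
            params, reference_hue=3.2, reference_background="blue",
            test_background="gray", levels=3.2 - shift + np.linspace(-0.3, 0.3, 7),
            n_per_level=2000, seed=21,
        )
        bias_gray = fit_gray.location - 3.2
        bias_blue = fit_blue.location - 3.2
        assert bias_gray == pytest.approx(shift, abs=0.02)
        assert bias_blue == pytest.approx(-shift, abs=0.02)
        assert abs(abs(bias_gray) - abs(bias_blue)) < 0.04

    def test_uniform_priors_and_no_memory_give_zero_bias(self, pse_estimator):
        """Uniform priors, kappa = 1: symmetric conditions are unbiased and
        the joint condition reduces to pure constancy."""
        params = ObserverParams(
            kappa_memory=1.0,
            prior_reflectance_sigma=INF,
            prior_illuminant_sigma=INF,
            lapse_rate=0.0,
            response_criterion=0.0,
        )
        shift = params.illuminant_shift_blue
        base = pse_estimator(
            params, reference_hue=3.2, levels=3.2 + np.linspace(-0.3, 0.3, 7),
            n_per_level=2000, seed=30,
        )
        mem = pse_estimator(
            params, reference_hue=3.2, delayed=True,
            levels=3.2 + np.linspace(-0.45, 0.45, 7), n_per_level=2000, seed=31,
        )
        joint = pse_estimator(
            params, reference_hue=3.2, reference_background="gray",
            test_background="blue", delayed=True,
            levels=3.2 + shift + np.linspace(-0.45, 0.45, 7),
            n_per_level=2000, seed=32,
        )
        assert base.location == pytest.approx(3.2, abs=0.015)
        assert mem.location == pytest.approx(3.2, abs=0.02)
        assert joint.location == pytest.approx(3.2 + shift, abs=0.02)


class TestBlockPriors:
    def test_prior_means_follow_block_statistics(self, default_params, reference_hues):
        gray = params_for_block(default_params, "gray", reference_hues)
        blue = params_for_block(default_params, "blue", reference_hues)
        asym = params_for_block(default_params, "asymmetric", reference_hues)
        assert gray.prior_reflectance_mean == pytest.approx(3.2)
        assert gray.prior_illuminant_mean == 0.0
        assert blue.prior_illuminant_mean == default_params.illuminant_shift_blue
        assert asym.prior_illuminant_mean == pytest.approx(
            default_params.illuminant_shift_blue / 2
        )

    def test_distractors_pull_reflectance_prior_yellow(self, default_params, reference_hues):
        plain = params_for_block(default_params, "gray", reference_hues)
        with_d = params_for_block(
            default_params, "gray", reference_hues, distractors=True, distractor_offset=0.2
        )
        assert with_d.prior_reflectance_mean == pytest.approx(
            plain.prior_reflectance_mean - 0.1
        )

    def test_unknown_block_background_rejected(self, default_params, reference_hues):
        with pytest.raises(InvalidParameterError):
            params_for_block(default_params, "plaid", reference_hues)
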