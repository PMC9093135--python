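"""Weibull MLE, transition probabilities and their closed-form oracles."""

import numpy as np
import pytest
from lifelines import WeibullFitter

from mucea.exceptions import InvalidInputError, NonIdentifiableError
from mucea.km_ipd import IPDRecord
from mucea.parametric_survival import (
    WeibullFit,
    fit_weibull,
    from_aft_params,
    median_survival,
    survival_at,
    to_aft_params,
    transition_probability,
)
from mucea.synthetic_data import simulate_ipd

TOY_T = np.array([1.0, 3.0, 4.0, 6.0, 8.0, 10.0])
TOY_E = np.array([1, 1, 0, 1, 0, 1])


def _loglik_grid(lam, gam, t, e):
    """Independent likelihood evaluation for the grid-search oracle."""
    lam = lam[:, None, None]
    gam = gam[None, :, None]
    t, e = t[None, None, :], e[None, None, :]
    terms = e * (np.log(lam) + np.log(gam) + (gam - 1) * np.log(t)) - lam * t**gam
    return terms.sum(axis=2)


class TestFit:
    def test_exponential_closed_form(self):
        t = np.array([2.0, 5.0, 1.0, 7.0, 3.0])
        e = np.ones(5, dtype=int)
        fit = fit_weibull((t, e), fix_gamma=1.0)
        assert fit.lambda_scale == pytest.approx(len(t) / t.sum(), rel=1e-12)
        assert fit.gamma_shape == 1.0

    def test_mle_matches_grid_search_oracle(self):
        fit = fit_weibull((TOY_T, TOY_E))
        # two-stage dense grid search, independent of the optimizer
        lam_grid = np.geomspace(1e-3, 1.0, 300)
        gam_grid = np.geomspace(0.2, 5.0, 300)
        ll = _loglik_grid(lam_grid, gam_grid, TOY_T, TOY_E)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        lam_grid = np.linspace(lam_grid[max(i - 1, 0)], lam_grid[min(i + 1, 299)], 500)
        gam_grid = np.linspace(gam_grid[max(j - 1, 0)], gam_grid[min(j + 1, 299)], 500)
        ll = _loglik_grid(lam_grid, gam_grid, TOY_T, TOY_E)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.lambda_scale == pytest.approx(lam_grid[i], abs=5e-4)
        assert fit.gamma_shape == pytest.approx(gam_grid[j], abs=5e-4)

    def test_parameter_recovery_under_censoring(self):
        # λ and γ are strongly correlated, so single-draw estimates wobble;
        # the estimator's accuracy is the median error over replicates
        errs = []
        for seed in range(9):
            ipd = simulate_ipd(0.02, 1.3, 5000, censor_rate=0.2, seed=seed,
                               arm="A", endpoint="OS")
            fit = fit_weibull(ipd)
            errs.append((abs(fit.lambda_scale - 0.02) / 0.02,
                         abs(fit.gamma_shape - 1.3) / 1.3))
        errs = np.array(errs)
        assert np.median(errs[:, 0]) <= 0.05
        assert np.median(errs[:, 1]) <= 0.05

    def test_agrees_with_lifelines(self):
        ipd = simulate_ipd(0.05, 1.4, 800, censor_rate=0.25, seed=5,
                           arm="A", endpoint="PFS")
        fit = fit_weibull(ipd)
        t = [r.time for r in ipd]
        e = [r.event for r in ipd]
        wf = WeibullFitter().fit(t, e)
        scale, shape = to_aft_params(fit)
        assert scale == pytest.approx(wf.lambda_, rel=1e-3)
        assert shape == pytest.approx(wf.rho_, rel=1e-3)
        back = from_aft_params(wf.lambda_, wf.rho_)
        assert back.lambda_scale == pytest.approx(fit.lambda_scale, rel=1e-2)

    def test_beats_exponential_submodel(self):
        ipd = simulate_ipd(0.03, 1.6, 400, seed=2, arm="A", endpoint="OS")
        full = fit_weibull(ipd)
        expo = fit_weibull(ipd, fix_gamma=1.0)
        assert full.log_likelihood >= expo.log_likelihood

    def test_zero_events_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_weibull((np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0])))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_weibull((np.array([0.0, 2.0]), np.array([1, 1])))


class TestFormulas:
    def test_survival_examples(self):
        fit = WeibullFit(lambda_scale=np.log(2), gamma_shape=1.0)
        assert survival_at(fit, 0.0) == 1.0
        assert survival_at(fit, 1.0) == pytest.approx(0.5, abs=1e-12)
        fit2 = WeibullFit(lambda_scale=0.05, gamma_shape=1.5)
        assert survival_at(fit2, 4.0) == pytest.approx(np.exp(-0.4), abs=1e-10)
        with pytest.raises(InvalidInputError):
            survival_at(fit, -1.0)

    def test_survival_strictly_decreasing(self):
        fit = WeibullFit(lambda_scale=0.07, gamma_shape=0.8)
        t = np.linspace(0.1, 60, 200)
        assert np.all(np.diff(survival_at(fit, t)) < 0)

    def test_transition_constant_hazard_limit(self):
        fit = WeibullFit(lambda_scale=0.1, gamma_shape=1.0)
        expected = 1 - np.exp(-0.1)
        for start in (0.0, 3.0, 17.0):
            assert transition_probability(fit, start, start + 1) == pytest.approx(
                expected, abs=1e-12
            )
        assert expected == pytest.approx(0.09516, abs=5e-6)

    def test_transition_direct_formula(self):
        fit = WeibullFit(lambda_scale=0.05, gamma_shape=1.5)
        expected = 1 - np.exp(0.05 * 2**1.5 - 0.05 * 3**1.5)
        assert transition_probability(fit, 2, 3) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.111647, abs=5e-6)

    def test_transition_equals_survival_ratio(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            # ranges keep S(t) well away from floating-point underflow
            fit = WeibullFit(lambda_scale=rng.uniform(0.005, 0.3),
                             gamma_shape=rng.uniform(0.4, 2.0))
            t = rng.uniform(0, 15)
            dt = rng.uniform(0.1, 3)
            direct = transition_probability(fit, t, t + dt)
            ratio = 1 - survival_at(fit, t + dt) / survival_at(fit, t)
            assert direct == pytest.approx(ratio, abs=1e-12)

    def test_transition_monotone_in_cycle_with_shape(self):
        increasing = WeibullFit(lambda_scale=0.02, gamma_shape=1.5)
        decreasing = WeibullFit(lambda_scale=0.02, gamma_shape=0.7)
        p_inc = [transition_probability(increasing, t, t + 1) for t in range(40)]
        p_dec = [transition_probability(decreasing, t, t + 1) for t in range(1, 40)]
        assert np.all(np.diff(p_inc) >= 0)
        assert np.all(np.diff(p_dec) <= 0)

    def test_reversed_interval_rejected(self):
        fit = WeibullFit(lambda_scale=0.1, gamma_shape=1.0)
        with pytest.raises(InvalidInputError):
            transition_probability(fit, 3, 2)

    def test_median_examples_and_self_consistency(self):
        assert median_survival(WeibullFit(np.log(2), 1.0)) == pytest.approx(1.0)
        assert median_survival(
            WeibullFit(np.log(2) / 14.3, 1.0)
        ) == pytest.approx(14.3, rel=1e-12)
        rng = np.random.default_rng(7)
        for _ in range(20):
            fit = WeibullFit(lambda_scale=rng.uniform(0.01, 0.4),
                             gamma_shape=rng.uniform(0.5, 2.5))
            assert survival_at(fit, median_survival(fit)) == pytest.approx(0.5, abs=1e-12)
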