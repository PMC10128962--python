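"""Tests for the chi-square objectives and the three estimation modes."""

import math

import numpy as np
import pytest

from gliopred import (
    Bounds,
    ConstraintPrior,
    FollowUp,
    ModelParams,
    NoCollapseError,
    PowerLaw,
    chi2,
    chi2_constraint,
    fit_constrained,
    fit_loose,
    fit_piecewise_linear,
    fit_plain,
    radius_at,
    regrowth_time,
)
from gliopred.fitting import _multistarts

from .conftest import random_valid_params


def make_followup(params, times, sigma=1.0, noise=None, pid="syn"):
    r = np.asarray(radius_at(params, np.asarray(times)), dtype=float)
    if noise is not None:
        r = r + noise
    return FollowUp(pid, tuple(zip(times, r)), sigma=sigma)


RICH_TIMES = np.linspace(-1.5, 6.0, 12)


class TestChi2:
    def test_zero_on_noiseless_data(self, by_id):
        p = by_id["0"].params
        fu = make_followup(p, RICH_TIMES)
        assert chi2(p, fu) == pytest.approx(0.0, abs=1e-20)

    def test_single_point_one_sigma_deviation(self):
        p = ModelParams(20.0, 1.0, 5.0, 1.0)
        fu = FollowUp("x", ((0.0, 20.0 + 2.0),), sigma=2.0)
        assert chi2(p, fu) == pytest.approx(1.0)

    def test_matches_term_by_term_sum(self, rng):
        p = ModelParams(22.0, 1.2, 8.0, 0.9)
        times = [-1.0, -0.2, 0.3, 1.1, 4.0]
        noise = rng.normal(0, 1, 5)
        fu = make_followup(p, times, sigma=0.8, noise=noise)
        expected = sum(
            (r - radius_at(p, t)) ** 2 / 0.8**2 for t, r in fu.measurements
        )
        assert chi2(p, fu) == pytest.approx(expected, rel=1e-12)


class TestChi2Constraint:
    def test_zero_at_prior_mean(self, prior):
        # T is orthogonal, so inverse(mu) is the raw ensemble mean
        p = ModelParams.from_array(prior.inverse(prior.mu))
        assert chi2_constraint(p, prior) == pytest.approx(0.0, abs=1e-18)

    def test_one_sigma_per_component_gives_four(self, prior):
        p = ModelParams.from_array(prior.inverse(prior.mu + prior.sigma))
        assert chi2_constraint(p, prior) == pytest.approx(4.0, rel=1e-9)

    def test_matches_bruteforce_matrix_multiply(self, prior, rng):
        p = ModelParams(24.0, 1.7, 9.0, 1.1)
        vec = p.as_array()
        expected = 0.0
        for i in range(4):
            xi = sum(prior.T[i, j] * vec[j] for j in range(4))
            expected += ((xi - prior.mu[i]) / prior.sigma[i]) ** 2
        assert chi2_constraint(p, prior) == pytest.approx(expected, rel=1e-12)


class TestFitPlain:
    def test_recovers_noiseless_reference_parameters(self, by_id):
        truth = by_id["0"].params
        fu = make_followup(truth, RICH_TIMES)
        res = fit_plain(fu)
        np.testing.assert_allclose(res.params.as_array(), truth.as_array(), atol=1e-3)
        assert res.converged and res.mode == "plain"

    def test_speed_clamps_to_bound_when_data_slope_is_faster(self):
        # data generated with v = 6 mm/yr: outside the physiological range
        t = np.linspace(-2, 4, 10)
        r = 20.0 + 6.0 * t - 5.0 * (1 - np.exp(-np.maximum(t, 0) / 1.0))
        fu = FollowUp("fast", tuple(zip(t, r)))
        res = fit_plain(fu)
        assert res.params.v == pytest.approx(4.0, abs=1e-6)

    def test_requires_four_points(self):
        fu = FollowUp("x", ((-0.5, 20.0), (0.0, 21.0), (0.25, 19.0)))
        with pytest.raises(ValueError, match="fit_constrained"):
            fit_plain(fu)

    def test_objective_not_above_any_start(self, by_id, rng):
        truth = by_id["6"].params
        fu = make_followup(truth, RICH_TIMES, noise=rng.normal(0, 1, len(RICH_TIMES)))
        res = fit_plain(fu)
        for x0 in _multistarts(fu, Bounds()):
            assert res.objective_value <= chi2(ModelParams.from_array(x0), fu) + 1e-9

    def test_parameter_recovery_median_tmin_error(self, ensemble, rng):
        # 12-point follow-ups with 1 mm noise: median |t_min error| < 0.3 yr
        errors = []
        entries = list(ensemble) * 3  # 60 draws > 50, params cycling Table rows
        for e in entries[:50]:
            noise = rng.normal(0, 1, len(RICH_TIMES))
            fu = make_followup(e.params, RICH_TIMES, noise=noise)
            res = fit_plain(fu)
            est = regrowth_time(res.params)
            truth = regrowth_time(e.params)
            if est is None:
                est = math.nan
            errors.append(abs(est - truth))
        assert np.median(errors) < 0.3


class TestFitConstrained:
    def test_total_objective_dominated_by_plain_solution(self, ensemble, prior):
        # the constrained optimum can never beat the plain optimum evaluated
        # under the total objective, and always beats it the other way round
        for e in list(ensemble)[:6]:
            fu = make_followup(e.params, RICH_TIMES)
            res_p = fit_plain(fu)
            res_c = fit_constrained(fu, prior)
            total_at_plain = chi2(res_p.params, fu) + chi2_constraint(res_p.params, prior)
            assert res_c.objective_value <= total_at_plain + 1e-6
            assert chi2(res_c.params, fu) >= res_p.objective_value - 1e-6

    def test_three_point_fit_of_slow_responder_is_prior_driven(self, by_id, prior):
        # slow responder measured at [-0.5, 0, 0.25] yr: the data carry no
        # curvature information, so the estimate falls near the prior's
        # typical regrowth time (~2 yr), far below the truth
        truth = by_id["14"].params  # t_min = 4.16 yr
        fu = make_followup(truth, [-0.5, 0.0, 0.25])
        res = fit_constrained(fu, prior)
        t_est = regrowth_time(res.params)
        assert 0.5 < t_est < 3.0

    def test_infinite_sigma_prior_reduces_to_plain(self, by_id, prior, rng):
        truth = by_id["2"].params
        noise = rng.normal(0, 1, len(RICH_TIMES))
        fu = make_followup(truth, RICH_TIMES, noise=noise)
        flat = ConstraintPrior(
            T=prior.T, mu=prior.mu, sigma=np.full(4, np.inf)
        )
        res_flat = fit_constrained(fu, flat)
        res_plain = fit_plain(fu)
        np.testing.assert_allclose(
            res_flat.params.as_array(), res_plain.params.as_array(), atol=1e-6
        )


class TestFitLoose:
    def test_unit_collapse_speed_returns_a(self):
        # piecewise-linear data with v_d = 1: v_d**b = 1 for any b
        t = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        r = 20.0 + 2.0 * t - 1.0 * np.maximum(t, 0)
        fu = FollowUp("x", tuple(zip(t, r)))
        assert fit_loose(fu, PowerLaw(9.0, 0.61)) == pytest.approx(9.0, rel=1e-9)

    def test_known_collapse_speed_applies_power_law(self):
        t = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        r = 20.0 + 2.0 * t - 4.0 * np.maximum(t, 0)
        fu = FollowUp("x", tuple(zip(t, r)))
        expected = 9.0 / 4.0**0.61  # independent calculator evaluation
        assert fit_loose(fu, (9.0, 0.61)) == pytest.approx(expected, rel=1e-9)

    def test_collapse_speed_near_truth_on_sparse_exponential_data(self, by_id):
        # noiseless 4-point clinical design on a slow responder: the
        # piecewise-linear model is a biased approximation of the
        # exponential decay, but v_d lands within 15% of k/tau
        truth = by_id["14"].params
        fu = make_followup(truth, [-0.5, 0.0, 0.25, 1.0])
        _, _, v_d = fit_piecewise_linear(fu)
        assert v_d == pytest.approx(truth.k / truth.tau, rel=0.16)

    @pytest.mark.parametrize("post_slope", [2.0, 3.5])
    def test_growing_tumor_raises_no_collapse(self, post_slope):
        # post-RT slope at or above the pre-RT one: v_d <= 0, no prediction
        t = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        r = 20.0 + 2.0 * t + (post_slope - 2.0) * np.maximum(t, 0)
        fu = FollowUp("x", tuple(zip(t, r)))
        with pytest.raises(NoCollapseError):
            fit_loose(fu, (9.0, 0.61))

    def test_needs_two_points_each_side(self):
        fu = FollowUp("x", ((-0.5, 20.0), (0.25, 19.0), (1.0, 18.0)))
        with pytest.raises(ValueError):
            fit_piecewise_linear(fu)


class TestBounds:
    def test_default_speed_range(self):
        b = Bounds()
        assert b.lower[1] == 0.5 and b.upper[1] == 4.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Bounds(lower=(1, 1, 1, 1), upper=(0.5, 2, 2, 2))
        with pytest.raises(ValueError):
            Bounds(lower=(-1, 0.5, 0, 0), upper=(10, 4, 10, 10))

    def test_multistart_count_and_feasibility(self, by_id):
        fu = make_followup(by_id["0"].params, RICH_TIMES)
        b = Bounds()
        starts = _multistarts(fu, b)
        lo, hi = b.arrays()
        assert starts.shape == (8, 4)
        assert np.all(starts > lo) and np.all(starts < hi)
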