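import math

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy.optimize import minimize

from pdl1time.survival import (
    NOT_REACHED,
    cox_multivariable,
    five_year_rate,
    km_estimate,
    logrank_test,
    reverse_km_followup,
    survival_at,
)
from pdl1time.synthetic import simulate_cox_frame


def _km_bruteforce(times, events):
    """Independent product-limit oracle: explicit loop over event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n = np.sum(times >= t)
        d = np.sum(events & (times == t))
        s *= 1 - d / n
        out[t] = s
    return out


class TestKmEstimate:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([5.0, 8.0, 13.0], [False, False, False])
        assert curve.times.size == 0
        assert survival_at(curve, 100.0) == 1.0

    def test_all_events_product_limit_by_hand(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_censoring_between_events(self):
        # the subject censored at 2 leaves the risk set, so the final event
        # has a risk set of one: S(3) = 2/3 * (1 - 1/1) = 0
        curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert survival_at(curve, 1.0) == pytest.approx(2 / 3)
        assert survival_at(curve, 2.5) == pytest.approx(2 / 3)
        assert survival_at(curve, 3.0) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            times = np.round(rng.exponential(20, size=n), 1)  # forces ties
            events = rng.random(n) < 0.7
            if not events.any():
                events[0] = True
            curve = km_estimate(times, events)
            oracle = _km_bruteforce(times, events)
            assert curve.times.tolist() == sorted(oracle)
            np.testing.assert_allclose(
                curve.survival, [oracle[t] for t in curve.times]
            )

    def test_matches_lifelines_on_random_instance(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(30, size=200)
        events = rng.random(200) < 0.6
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [5.0, 20.0, 60.0]:
            assert survival_at(curve, t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestSurvivalAt:
    def test_time_zero_is_one(self):
        curve = km_estimate([1.0, 2.0], [True, True])
        assert survival_at(curve, 0.0) == 1.0

    def test_right_continuity_and_step_extension(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        assert survival_at(curve, 2.5) == survival_at(curve, 1.0)
        assert survival_at(curve, 1e9) == curve.survival[-1]

    def test_negative_time_rejected(self):
        curve = km_estimate([1.0], [True])
        with pytest.raises(ValueError):
            survival_at(curve, -0.1)

    def test_non_increasing_in_t(self):
        rng = np.random.default_rng(17)
        curve = km_estimate(rng.exponential(10, 50), rng.random(50) < 0.5)
        grid = np.linspace(0, 50, 200)
        values = [survival_at(curve, t) for t in grid]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        stat, p = logrank_test({"a": (t, e), "b": (t, e)})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_complete_separation_is_highly_significant(self):
        a = (list(np.linspace(1, 10, 50)), [True] * 50)
        b = (list(np.linspace(100, 110, 50)), [True] * 50)
        _, p = logrank_test({"a": a, "b": b})
        assert p < 0.001

    def test_two_group_statistic_matches_manual_oe_calculation(self):
        # small instance with distinct event times: chi2 = (O-E)^2/V by hand
        groups = {
            "a": ([1.0, 3.0, 5.0, 7.0], [True, True, False, True]),
            "b": ([2.0, 4.0, 6.0, 8.0], [True, False, True, False]),
        }
        times = np.array([1, 3, 5, 7, 2, 4, 6, 8], float)
        events = np.array([1, 1, 0, 1, 1, 0, 1, 0], bool)
        is_a = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        o_minus_e, var = 0.0, 0.0
        for t in sorted(times[events]):
            at_risk = times >= t
            n, n1 = at_risk.sum(), (at_risk & is_a).sum()
            d = (events & (times == t)).sum()
            d1 = (events & (times == t) & is_a).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e ** 2 / var
        stat, _ = logrank_test(groups)
        assert stat == pytest.approx(expected_chi2, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero members"):
            logrank_test({"a": ([1.0], [True]), "b": ([], [])})


class TestReverseKm:
    def test_all_censored_at_sixty(self):
        assert reverse_km_followup([60.0] * 5, [False] * 5) == 60.0

    def test_all_events_median_not_reached(self):
        assert reverse_km_followup([1.0, 2.0], [True, True]) is NOT_REACHED

    def test_half_censored_half_events(self):
        times = [24.0] * 5 + [100.0] * 5
        events = [False] * 5 + [True] * 5
        assert reverse_km_followup(times, events) == 24.0


def _neg_log_partial_likelihood(beta, x, times, events):
    """Hand-written Cox partial likelihood (no ties in the data)."""
    beta = np.atleast_1d(beta)
    eta = x @ beta
    nll = 0.0
    for i in np.nonzero(events)[0]:
        risk = times >= times[i]
        nll -= eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return nll


class TestCoxMultivariable:
    def test_one_covariate_matches_gridsearch_partial_likelihood(self):
        rng = np.random.default_rng(21)
        n = 60
        x = rng.normal(size=(n, 1))
        times = rng.exponential(np.exp(-0.8 * x[:, 0]))
        events = np.ones(n, dtype=bool)
        df = pd.DataFrame({"time": times, "event": events, "x": x[:, 0]})
        est = cox_multivariable(df, "x", covariates=[])[0]
        grid = np.arange(-3, 3, 1e-3)
        nll = [_neg_log_partial_likelihood(b, x, times, events) for b in grid]
        beta_grid = grid[int(np.argmin(nll))]
        assert math.log(est.hr) == pytest.approx(beta_grid, abs=2e-3)

    def test_two_covariates_match_bruteforce_likelihood_optimum(self):
        rng = np.random.default_rng(31)
        n = 80
        x = rng.normal(size=(n, 2))
        times = rng.exponential(np.exp(-(0.5 * x[:, 0] - 0.7 * x[:, 1])))
        events = np.ones(n, dtype=bool)
        df = pd.DataFrame({"time": times, "event": events,
                           "x1": x[:, 0], "x2": x[:, 1]})
        ests = cox_multivariable(df, "x1", covariates=["x2"])
        res = minimize(
            _neg_log_partial_likelihood, np.zeros(2),
            args=(x, times, events), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        fitted = [math.log(e.hr) for e in ests]
        np.testing.assert_allclose(fitted, res.x, atol=1e-3)

    def test_null_indicator_recovers_hr_near_one(self):
        df = simulate_cox_frame(1500, hazard_ratio=1.0, seed=4)
        est = cox_multivariable(df, "indicator")[0]
        assert est.ci_low < 1.0 < est.ci_high
        assert 0.8 < est.hr < 1.25

    def test_generating_hr_recovered_single_seed(self):
        df = simulate_cox_frame(2000, hazard_ratio=0.5, seed=0)
        est = cox_multivariable(df, "indicator")[0]
        assert 0.4 <= est.hr <= 0.6
        assert est.ci_low <= est.hr <= est.ci_high

    def test_missing_covariates_complete_case_excluded(self):
        df = simulate_cox_frame(300, hazard_ratio=1.0, seed=2)
        df.loc[:9, "age"] = np.nan
        ests = cox_multivariable(df, "indicator")
        assert len(ests) >= 9  # indicator + dummy-encoded covariates
        assert ests[0].variable == "indicator"


def test_five_year_rate_reads_curve_at_sixty_months():
    curve = km_estimate([30.0, 70.0], [True, True])
    assert five_year_rate(curve) == pytest.approx(0.5)
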