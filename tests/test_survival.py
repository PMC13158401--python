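import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from lrmscore.survival import (
    cox_hr_binary,
    km_estimate,
    logrank_hr_approx,
    median_ratio_bootstrap,
    stratify_by_median,
    weighted_logrank,
    _km_median,
)

from conftest import single_marker_cohort


class TestStratifyByMedian:
    def test_even_n(self):
        t = single_marker_cohort([1, 2, 3, 4], [0, 0, 1, 1])
        np.testing.assert_array_equal(stratify_by_median(t, "m"), [0, 0, 1, 1])

    def test_value_at_median_goes_low(self):
        t = single_marker_cohort([1, 2, 3], [0, 0, 1])
        np.testing.assert_array_equal(stratify_by_median(t, "m"), [0, 0, 1])

    def test_25_patients_split_13_12(self):
        rng = np.random.default_rng(0)
        t = single_marker_cohort(rng.normal(size=25) ** 2, rng.integers(0, 2, 25))
        g = stratify_by_median(t, "m")
        assert sorted([g.sum(), 25 - g.sum()]) == [12, 13]

    def test_constant_marker_errors(self):
        t = single_marker_cohort([2, 2, 2, 2], [0, 0, 1, 1])
        with pytest.raises(ValueError):
            stratify_by_median(t, "m")


class TestKmEstimate:
    def test_hand_example_with_censoring(self):
        fit = km_estimate([5, 8, 12, 16, 23], [0, 1, 1, 0, 1])
        assert fit.survival_at(8) == pytest.approx(0.75)
        assert fit.survival_at(12) == pytest.approx(0.50)
        assert fit.survival_at(23) == pytest.approx(0.0)
        assert fit.median_os == 12

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(100, 31)
        fit = km_estimate(times, np.ones(31, int))
        for t in np.percentile(times, [10, 50, 90]):
            assert fit.survival_at(t) == pytest.approx((times > t).mean())
        assert fit.median_os == pytest.approx(np.sort(times)[15])

    def test_all_censored_flagged(self):
        fit = km_estimate([3, 6, 9], [0, 0, 0])
        assert fit.median_os is None
        assert fit.survival_at(100) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_fast_median_agrees_with_lifelines(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            times = rng.exponential(50, n).round(1)
            events = rng.integers(0, 2, n)
            fast = _km_median(times, events)
            full = km_estimate(times, events).median_os
            assert fast == full


class TestWeightedLogrank:
    def test_duplicated_groups_are_null(self):
        t = [3, 5, 7, 9]
        e = [1, 1, 0, 1]
        r = weighted_logrank(t + t, e + e, [0] * 4 + [1] * 4)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(50, 20)
        e = rng.integers(0, 2, 20)
        e[:4] = 1
        g = np.r_[np.zeros(10, int), np.ones(10, int)]
        for w in ("logrank", "gehan"):
            a = weighted_logrank(t, e, g, w)
            b = weighted_logrank(t, e, 1 - g, w)
            assert a.chi2 == pytest.approx(b.chi2, rel=1e-10)

    def test_six_patient_toy_matches_hand_table(self):
        # group 0: events at 1, 3; group 1: events at 2, 4; censored 5, 6.
        # Hand hypergeometric table (O-E for group 1):
        # t=1: n=6, n1=3, d=1, E=0.5, V=0.25
        # t=2: n=5, n1=3, d=1, E=0.6, V=0.24
        # t=3: n=4, n1=2, d=1, E=0.5, V=0.25
        # t=4: n=3, n1=2, d=1, E=2/3, V=2/9
        # O1=2, sum E=2.2667, sum V=0.96222 -> chi2 = (2-2.2667)^2/0.96222
        times = [1, 3, 2, 4, 5, 6]
        events = [1, 1, 1, 1, 0, 0]
        group = [0, 0, 1, 1, 0, 1]
        r = weighted_logrank(times, events, group)
        expected = (2 - 2.2666666666666666) ** 2 / 0.9622222222222222
        assert r.chi2 == pytest.approx(expected, abs=1e-10)

    def test_gehan_weights_early_events(self):
        # one group with early events and long tails: gehan and logrank differ
        times = [1, 2, 3, 50, 60, 70, 80, 90]
        events = [1, 1, 1, 1, 1, 1, 1, 1]
        group = [1, 1, 1, 0, 0, 0, 0, 1]
        a = weighted_logrank(times, events, group, "logrank")
        b = weighted_logrank(times, events, group, "gehan")
        assert a.chi2 != pytest.approx(b.chi2)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            weighted_logrank([1, 2], [0, 0], [0, 1])


class TestCoxHrBinary:
    def test_identical_groups_unit_hr(self):
        t = [3, 5, 7, 9]
        e = [1, 1, 0, 1]
        r = cox_hr_binary(t + t, e + e, [0] * 4 + [1] * 4)
        assert r.hr == pytest.approx(1.0, abs=1e-6)
        assert r.ci_low < 1.0 < r.ci_high

    def test_two_event_toy_matches_partial_likelihood_grid(self):
        # times 1 (event, group 1), 2 (event, group 0), 3 (censored, group 1)
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 0])
        group = np.array([1, 0, 1])

        def neg_pl(b):
            # risk set at t=1: {1,0,1}; at t=2: {0,1}
            import numpy as _np

            l1 = b - _np.log(_np.exp(b) + 1 + _np.exp(b))
            l2 = 0 - _np.log(1 + _np.exp(b))
            return -(l1 + l2)

        res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        r = cox_hr_binary(times, events, group)
        assert math.log(r.hr) == pytest.approx(res.x, abs=1e-6)

    def test_group_swap_negates_log_hr(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(30, 40)
        e = np.ones(40, int)
        g = np.r_[np.zeros(20, int), np.ones(20, int)]
        t[g == 1] *= 0.4
        a = cox_hr_binary(t, e, g)
        b = cox_hr_binary(t, e, 1 - g)
        assert math.log(a.hr) == pytest.approx(-math.log(b.hr), abs=1e-6)

    def test_bias_shrinks_with_n(self):
        """Planted log-HR recovered with decreasing bias at growing n."""
        true = math.log(2.0)
        bias = []
        for i, n in enumerate((100, 1000)):
            rng = np.random.default_rng(40 + i)
            g = np.r_[np.zeros(n, int), np.ones(n, int)]
            t = rng.exponential(np.where(g == 1, 1 / math.exp(true), 1.0))
            r = cox_hr_binary(t, np.ones(2 * n, int), g)
            bias.append(abs(math.log(r.hr) - true))
        assert bias[1] < max(bias[0], 0.08)

    def test_monotone_likelihood_flagged(self):
        # every group-1 event precedes every group-0 event
        times = [1, 2, 3, 10, 11, 12]
        events = [1, 1, 1, 1, 1, 1]
        group = [1, 1, 1, 0, 0, 0]
        r = cox_hr_binary(times, events, group)
        assert r.unbounded or r.hr > 50


class TestMedianRatio:
    def test_ratio_and_ci_cover_point(self):
        rng = np.random.default_rng(8)
        g = np.r_[np.zeros(40, int), np.ones(40, int)]
        t = rng.exponential(np.where(g == 1, 50, 200))
        r = median_ratio_bootstrap(t, np.ones(80, int), g, n_boot=300, seed=1)
        assert r.ratio is not None and r.ratio > 1
        assert r.ci_low <= r.ratio <= r.ci_high

    def test_oe_ratio_hr_positive_direction(self):
        rng = np.random.default_rng(9)
        g = np.r_[np.zeros(50, int), np.ones(50, int)]
        t = rng.exponential(np.where(g == 1, 30, 100))
        assert logrank_hr_approx(t, np.ones(100, int), g) > 1
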