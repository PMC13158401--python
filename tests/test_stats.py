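import math

import numpy as np
import pandas as pd
import pytest

from lrmscore.stats import (
    DegenerateInputError,
    compute_auroc,
    confusion_metrics,
    delong_compare,
    delong_se,
    fast_auroc,
    univariate_marker_stats,
)

from conftest import single_marker_cohort


class TestComputeAuroc:
    def test_pair_counting_hand_example(self):
        # HCC {1,2,3}, iCCA {2,3,4}: 6 concordant + 2 tied of 9 pairs
        r = compute_auroc([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        assert r.auroc == pytest.approx((6 + 0.5 * 2) / 9)

    def test_bounds_and_constant_scores(self):
        assert compute_auroc([1, 2, 3, 4], [0, 0, 1, 1]).auroc == 1.0
        assert compute_auroc([5, 5, 5, 5], [0, 1, 0, 1]).auroc == 0.5

    def test_trapezoid_identity_on_random_tied_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 6, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = compute_auroc(scores, labels)
            assert abs(r.auroc - r.auroc_trapezoid) < 1e-12
            assert r.auroc == fast_auroc(scores, labels)

    def test_sign_reversal_and_label_swap(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        a = compute_auroc(scores, labels).auroc
        assert compute_auroc(-scores, labels).auroc == pytest.approx(1 - a)
        assert compute_auroc(scores, 1 - labels).auroc == pytest.approx(1 - a)

    def test_single_class_errors(self):
        with pytest.raises(DegenerateInputError):
            compute_auroc([1, 2], [1, 1])

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.integers(0, 5, 50).astype(float)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert compute_auroc(scores, labels).auroc == pytest.approx(
            roc_auc_score(labels, scores)
        )


class TestDeLong:
    def test_self_comparison_null(self):
        r = delong_compare([1, 2, 3, 4], [1, 2, 3, 4], [0, 1, 0, 1])
        assert r.z == 0.0 and r.p == 1.0 and r.degenerate

    def test_placements_match_hand_midranks(self):
        # 2 positives {3, 1}, 2 negatives {2, 1}: V10 = (1.0, 0.25), V01 = (0.5, 0.75)
        scores = np.array([3.0, 1.0, 2.0, 1.0])
        labels = np.array([1, 1, 0, 0])
        from lrmscore.stats import _placements

        v10, v01 = _placements(scores, labels)
        np.testing.assert_allclose(v10, [1.0, 0.25])
        np.testing.assert_allclose(v01, [0.5, 0.75])
        r = delong_compare(scores, scores, labels)
        assert r.auroc_a == pytest.approx(np.mean([1.0, 0.25]))

    def test_variance_matches_bootstrap(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=24) + np.r_[np.zeros(12), np.full(12, 1.2)]
        labels = np.r_[np.zeros(12, int), np.ones(12, int)]
        se = delong_se(scores, labels)
        boots = np.empty(10_000)
        i0, i1 = np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)
        for b in range(10_000):
            take = np.r_[rng.choice(i0, 12), rng.choice(i1, 12)]
            boots[b] = fast_auroc(scores[take], labels[take])
        assert se**2 == pytest.approx(boots.var(ddof=1), rel=0.15)

    def test_two_sided_p_for_distinct_models(self):
        rng = np.random.default_rng(22)
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        good = labels + rng.normal(0, 0.4, 40)
        noise = rng.normal(size=40)
        r = delong_compare(good, noise, labels)
        assert r.auroc_a > r.auroc_b
        assert 0 < r.p < 0.05


class TestConfusionMetrics:
    def test_hand_derived_chi2(self):
        pred = [1] * 22 + [0] * 3 + [1] * 3 + [0] * 22
        truth = [1] * 25 + [0] * 25
        r = confusion_metrics(pred, truth)
        assert (r.tp, r.fn, r.fp, r.tn) == (22, 3, 3, 22)
        assert r.sensitivity == pytest.approx(0.88)
        assert r.specificity == pytest.approx(0.88)
        assert r.chi2 == pytest.approx(28.88)
        assert r.p < 0.0001

    def test_perfect_prediction(self):
        r = confusion_metrics([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert r.sensitivity == r.specificity == r.ppv == r.npv == 1.0

    def test_degenerate_margin_flagged_undefined(self):
        r = confusion_metrics([1] * 6, [1] * 3 + [0] * 3)
        assert r.specificity == 0.0
        assert r.npv is None

    def test_scipy_cross_check(self):
        from scipy.stats import chi2_contingency

        pred = [1] * 20 + [0] * 5 + [1] * 8 + [0] * 17
        truth = [1] * 25 + [0] * 25
        r = confusion_metrics(pred, truth)
        chi2, p, _, _ = chi2_contingency(
            [[r.tp, r.fn], [r.fp, r.tn]], correction=False
        )
        assert r.chi2 == pytest.approx(chi2)
        assert r.p == pytest.approx(p)

    def test_label_swap_maps_sens_to_spec(self):
        pred = np.array([1, 0, 1, 1, 0, 0])
        truth = np.array([1, 1, 0, 1, 0, 0])
        a = confusion_metrics(pred, truth)
        b = confusion_metrics(1 - pred, 1 - truth)
        assert a.sensitivity == b.specificity and a.specificity == b.sensitivity


class TestUnivariateMarkerStats:
    def test_identical_groups_are_null(self):
        t = single_marker_cohort([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        s = univariate_marker_stats(t).loc["m"]
        assert s["welch_t"] == 0 and s["welch_p"] == pytest.approx(1.0)
        assert s["cohens_d"] == 0 and s["auroc"] == 0.5

    def test_hand_computed_toy(self):
        t = single_marker_cohort([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        s = univariate_marker_stats(t).loc["m"]
        assert s["welch_t"] == pytest.approx(3.0 / math.sqrt(2.0 / 3.0), abs=1e-10)
        assert s["cohens_d"] == pytest.approx(3.0)
        assert s["mwu_p"] == pytest.approx(0.1)  # exact enumeration: 2/20
        assert s["fold_change"] == pytest.approx(5.0 / 2.0)

    def test_scale_equivariance(self):
        vals = np.array([1.0, 2.5, 3.0, 4.0, 6.0, 9.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        a = univariate_marker_stats(single_marker_cohort(vals, labels)).loc["m"]
        b = univariate_marker_stats(single_marker_cohort(vals * 10, labels)).loc["m"]
        for col in ("welch_p", "mwu_p", "cohens_d", "auroc", "power"):
            assert a[col] == pytest.approx(b[col], abs=1e-12)

    def test_degenerate_marker_flagged_not_fatal(self):
        import pandas as pd

        from lrmscore.cohort import CohortTable
        from lrmscore.markers import MarkerSpec

        t = CohortTable(
            patient_id=pd.Index(list("abcdef")),
            label=np.array([0, 0, 0, 1, 1, 1]),
            markers=pd.DataFrame(
                {"good": [1.0, 2, 3, 4, 5, 6], "bad": [1.0, np.nan, np.nan, 2, 3, 4]}
            ),
            specs=[
                MarkerSpec("good", "u", "serology", allow_missing=True),
                MarkerSpec("bad", "u", "serology", allow_missing=True),
            ],
        )
        s = univariate_marker_stats(t)
        assert s.loc["bad", "flagged"]
        assert not s.loc["good", "flagged"]
        assert np.isfinite(s.loc["good", "auroc"])
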