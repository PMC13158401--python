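import math

import numpy as np
import pandas as pd
import pytest

from lrmscore.prioritize import (
    LogisticModel,
    default_lambda_grid,
    fit_l1_logistic,
    kkt_residual,
    l1_objective,
    lambda_max,
    lasso_path,
    logistic_predict,
    merge_rankings,
    pca_contribution,
    refit_ridge_logistic,
)


def _random_instance(rng, n=30, d=4):
    X = rng.standard_normal((n, d))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = rng.normal(0, 1.5, d) * rng.integers(0, 2, d)
    p = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


class TestFitL1Logistic:
    def test_null_model_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X, y = _random_instance(rng)
        lam = lambda_max(X, y)
        m = fit_l1_logistic(X, y, lam * 1.0001)
        assert np.all(m.coef == 0)
        assert m.intercept == pytest.approx(math.log(y.mean() / (1 - y.mean())))
        assert kkt_residual(X, y, m.intercept, m.coef, m.penalty) <= 1e-6

    def test_one_feature_toy_matches_grid_oracle(self):
        # labels match the sign of the single +/-1 feature; by symmetry the
        # optimal intercept is 0, so a dense 1-d grid is an exact oracle
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        lam = 0.1
        grid = np.arange(-5, 5, 1e-3)
        objs = [l1_objective(X, y, 0.0, np.array([b]), lam) for b in grid]
        oracle = grid[int(np.argmin(objs))]
        m = fit_l1_logistic(X, y, lam)
        assert m.coef[0] == pytest.approx(oracle, abs=1e-2)
        assert abs(m.intercept) < 1e-4

    def test_column_negation_flips_coefficient(self):
        rng = np.random.default_rng(1)
        X, y = _random_instance(rng, d=3)
        lam = 0.05
        m1 = fit_l1_logistic(X, y, lam)
        X2 = X.copy()
        X2[:, 1] *= -1
        m2 = fit_l1_logistic(X2, y, lam)
        assert m2.coef[1] == pytest.approx(-m1.coef[1], abs=1e-6)
        assert l1_objective(X, y, m1.intercept, m1.coef, lam) == pytest.approx(
            l1_objective(X2, y, m2.intercept, m2.coef, lam), abs=1e-10
        )

    def test_objective_below_null_and_kkt_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            X, y = _random_instance(rng, n=25, d=3)
            lam = 10 ** rng.uniform(-3, -0.5)
            m = fit_l1_logistic(X, y, lam)
            b0_null = math.log(y.mean() / (1 - y.mean()))
            assert l1_objective(X, y, m.intercept, m.coef, lam) <= l1_objective(
                X, y, b0_null, np.zeros(X.shape[1]), lam
            ) + 1e-12
            assert kkt_residual(X, y, m.intercept, m.coef, lam) <= 1e-6 * max(1, lam)

    def test_sklearn_saga_cross_check(self):
        """Independent solver route: sklearn saga with C = 1/(n*lam)."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X, y = _random_instance(rng, n=60, d=4)
        lam = 0.03
        mine = fit_l1_logistic(X, y, lam)
        sk = LogisticRegression(
            solver="saga", l1_ratio=1.0, C=1.0 / (len(y) * lam), tol=1e-10,
            max_iter=200_000,
        ).fit(X, y.astype(int))
        np.testing.assert_allclose(mine.coef, sk.coef_[0], atol=5e-3)
        assert mine.intercept == pytest.approx(sk.intercept_[0], abs=5e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_l1_logistic(np.ones((4, 1)), np.ones(4), 0.1)


class TestLogisticPredict:
    def test_null_model_predicts_half(self):
        m = LogisticModel(0.0, np.zeros(2), 0.0, ["a", "b"])
        np.testing.assert_allclose(logistic_predict(m, np.random.randn(5, 2)), 0.5)

    def test_sigmoid_arithmetic_and_monotonicity(self):
        m = LogisticModel(0.0, np.array([1.0]), 0.0, ["a"])
        p = logistic_predict(m, np.array([[0.0], [math.log(3)], [50.0]]))
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(0.75)
        assert p[2] > 0.999 and np.all(np.diff(p) > 0)

    def test_column_mismatch(self):
        m = LogisticModel(0.0, np.zeros(2), 0.0, ["a", "b"])
        with pytest.raises(ValueError):
            logistic_predict(m, np.zeros((3, 3)))


class TestLassoPath:
    def test_all_zero_at_top_and_signal_enters_first(self):
        rng = np.random.default_rng(5)
        n = 80
        signal = np.r_[-np.ones(n // 2), np.ones(n // 2)]
        noise = rng.standard_normal(n) * 0.05
        X = np.c_[signal + rng.standard_normal(n) * 0.3, noise]
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        grid = default_lambda_grid(X, y, n_points=20)
        grid[0] = lambda_max(X, y) * 1.01
        path = lasso_path(X, y, grid, ["sig", "noise"])
        assert np.all(path.coefs[0] == 0)
        assert "sig" in path.entry_lambda
        assert path.entry_lambda["sig"] > path.entry_lambda.get("noise", 0.0)

    def test_small_lambda_end_approximates_unpenalized_fit(self):
        rng = np.random.default_rng(8)
        n = 200
        X = rng.standard_normal((n, 2))
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1])))
        y = (rng.random(n) < p).astype(float)
        grid = default_lambda_grid(X, y, n_points=15, ratio=1e-5)
        path = lasso_path(X, y, grid)
        unpen = refit_ridge_logistic(X, y, ["a", "b"], l2=0.0)
        np.testing.assert_allclose(path.coefs[-1], unpen.coef, atol=1e-2)

    def test_path_continuity_under_refinement(self):
        rng = np.random.default_rng(13)
        X, y = _random_instance(rng, n=40, d=3)
        grid = default_lambda_grid(X, y, n_points=60, ratio=1e-2)
        path = lasso_path(X, y, grid)
        jumps = np.abs(np.diff(path.coefs, axis=0)).max()
        assert jumps < 0.25


class TestPcaContribution:
    def test_two_identical_columns(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        a = (a - a.mean()) / a.std(ddof=1)
        X = np.c_[a, a]
        c = pca_contribution(X, K=1, marker_names=["a", "b"])
        assert c["a"] == pytest.approx(1 / math.sqrt(2), abs=1e-10)
        assert c["b"] == pytest.approx(1 / math.sqrt(2), abs=1e-10)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        for d in (4, 9):
            X = rng.standard_normal((60, d))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            K = min(4, d)
            c = pca_contribution(X, K=K)
            cov = np.cov(X, rowvar=False, ddof=1)
            w, v = np.linalg.eigh(cov)
            order = np.argsort(w)[::-1]
            oracle = np.abs(v[:, order[:K]]).sum(axis=1)
            np.testing.assert_allclose(c.to_numpy(), oracle, atol=1e-10)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            pca_contribution(np.random.randn(10, 3), K=4)


class TestMergeRankings:
    def _model(self, coefs, names):
        return LogisticModel(0.0, np.array(coefs, dtype=float), 0.1, names)

    def test_support_only_when_q_zero(self):
        names = ["a", "b", "c"]
        m = self._model([0.5, -1.2, 0.1], names)
        contrib = pd.Series([0.1, 0.2, 0.9], index=names)
        r = merge_rankings(m, contrib, q=0)
        assert set(r.selected) == {"a", "b", "c"}
        assert list(r.table.index) == ["b", "a", "c"]  # |coef| descending

    def test_contribution_fallback_when_coefs_zero(self):
        names = ["a", "b", "c", "d"]
        m = self._model([0, 0, 0, 0], names)
        contrib = pd.Series([0.4, 0.9, 0.1, 0.6], index=names)
        r = merge_rankings(m, contrib, q=3)
        assert set(r.selected) == {"b", "d", "a"}
        assert list(r.table.index) == ["b", "d", "a", "c"]

    def test_union_rule_brute_force_order(self):
        names = ["A", "B", "C", "D"]
        m = self._model([0.3, 0.8, 0.0, 0.0], names)
        contrib = pd.Series({"A": 0.1, "B": 0.9, "C": 0.8, "D": 0.2})
        r = merge_rankings(m, contrib, q=2)
        assert set(r.selected) == {"A", "B", "C"}
        # brute-force check of the lexicographic ordering rule
        coef = dict(zip(names, m.coef))
        expected = sorted(
            names, key=lambda mk: (coef[mk] == 0, -abs(coef[mk]), -contrib[mk], mk)
        )
        assert list(r.table.index) == expected
        assert list(r.table["rank"]) == [1, 2, 3, 4]

    def test_q_out_of_range(self):
        names = ["a"]
        m = self._model([1.0], names)
        with pytest.raises(ValueError):
            merge_rankings(m, pd.Series({"a": 1.0}), q=2)
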