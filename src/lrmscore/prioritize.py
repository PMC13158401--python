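"""Data-driven marker prioritization.

Two complementary views are merged: (1) L1-penalized logistic regression on
the standardized marker matrix selects sparse discriminative predictors of
iCCA vs HCC; (2) PCA contribution scores (sum of absolute loadings over the
first K = 4 components) summarize each marker's share of the unsupervised
variance structure. The final panel is the union of the L1 support with the
top-q contributors.

The L1 fit minimizes

    (1/n) * sum_i log(1 + exp(-(2 y_i - 1) * (b0 + x_i . beta))) + lam * ||beta||_1

with an unpenalized intercept, by FISTA (accelerated proximal gradient with
restart). The contract is the objective and its KKT conditions, checked at
tolerance, not the particular algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

MAX_ITER = 100_000
TOL = 1e-8


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LogisticModel:
    intercept: float
    coef: np.ndarray
    penalty: float
    marker_names: list[str]
    iterations: int = 0
    converged: bool = True

    def support(self) -> list[str]:
        return [m for m, b in zip(self.marker_names, self.coef) if b != 0.0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def l1_objective(X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, lam: float) -> float:
    """Mean negative log-likelihood plus L1 penalty (intercept unpenalized)."""
    z = b0 + X @ beta
    # log(1 + exp(-s*z)) with s = +/-1, computed stably
    s = 2.0 * y - 1.0
    nll = np.logaddexp(0.0, -s * z).mean()
    return float(nll + lam * np.abs(beta).sum())


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero:
    max_j |(1/n) sum_i x_ij (y_i - ybar)|."""
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / len(y))


def _grad(X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray):
    p = _sigmoid(b0 + X @ beta)
    r = (p - y) / len(y)
    return r.sum(), X.T @ r


def fit_l1_logistic(
    X,
    y,
    lam: float,
    marker_names: list[str] | None = None,
    *,
    init: tuple[float, np.ndarray] | None = None,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> LogisticModel:
    """L1-penalized logistic fit by FISTA with adaptive restart.

    Deterministic for fixed inputs; stops once the KKT residual falls below
    ``tol`` (scaled by max(1, lam)). Raises ConvergenceError past the
    iteration cap.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    n, d = X.shape
    if marker_names is None:
        marker_names = [f"x{j}" for j in range(d)]

    ybar = y.mean()
    b0 = math.log(ybar / (1.0 - ybar))
    beta = np.zeros(d)
    if lam >= lambda_max(X, y) and init is None:
        # exact null solution by KKT
        return LogisticModel(b0, beta, lam, list(marker_names), 0, True)
    if init is not None:
        b0, beta = init[0], init[1].copy()

    # Lipschitz constant of the smooth part's gradient
    Xa = np.hstack([np.ones((n, 1)), X])
    L = (np.linalg.norm(Xa, 2) ** 2) / (4.0 * n)
    step = 1.0 / L

    vb0, vbeta = b0, beta.copy()
    t_mom = 1.0
    prev_obj = l1_objective(X, y, b0, beta, lam)
    for it in range(1, max_iter + 1):
        g0, g = _grad(X, y, vb0, vbeta)
        b0_new = vb0 - step * g0
        u = vbeta - step * g
        beta_new = np.sign(u) * np.maximum(np.abs(u) - step * lam, 0.0)

        obj = l1_objective(X, y, b0_new, beta_new, lam)
        if obj > prev_obj:  # adaptive restart
            vb0, vbeta, t_mom = b0, beta.copy(), 1.0
            g0, g = _grad(X, y, vb0, vbeta)
            b0_new = vb0 - step * g0
            u = vbeta - step * g
            beta_new = np.sign(u) * np.maximum(np.abs(u) - step * lam, 0.0)
            obj = l1_objective(X, y, b0_new, beta_new, lam)

        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom * t_mom))
        vb0 = b0_new + (t_mom - 1.0) / t_new * (b0_new - b0)
        vbeta = beta_new + (t_mom - 1.0) / t_new * (beta_new - beta)
        b0, beta, t_mom, prev_obj = b0_new, beta_new, t_new, obj

        if it % 10 == 0 or it < 10:
            if kkt_residual(X, y, b0, beta, lam) <= tol * max(1.0, lam):
                return LogisticModel(b0, beta, lam, list(marker_names), it, True)
    res = kkt_residual(X, y, b0, beta, lam)
    raise ConvergenceError(
        f"L1 logistic fit did not converge in {max_iter} iterations "
        f"(KKT residual {res:.3e}, lambda {lam:.3e})"
    )


def kkt_residual(X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, lam: float) -> float:
    """Max violation of the subgradient optimality conditions."""
    g0, g = _grad(X, y, b0, beta)
    res = abs(g0)
    nz = beta != 0
    if nz.any():
        res = max(res, float(np.max(np.abs(g[nz] + lam * np.sign(beta[nz])))))
    if (~nz).any():
        res = max(res, float(np.max(np.maximum(np.abs(g[~nz]) - lam, 0.0))))
    return res


def logistic_predict(model: LogisticModel, X) -> np.ndarray:
    """Predicted iCCA probabilities 1/(1+exp(-(b0 + x.beta)))."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.coef):
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {len(model.coef)}"
        )
    return _sigmoid(model.intercept + X @ model.coef)


@dataclass
class LassoPath:
    lambdas: np.ndarray  # decreasing
    coefs: np.ndarray  # len(lambdas) x d
    intercepts: np.ndarray
    marker_names: list[str]
    entry_lambda: dict[str, float]  # first (largest) lambda with nonzero coef


def lasso_path(X, y, lam_grid, marker_names: list[str] | None = None) -> LassoPath:
    """Penalized-logistic coefficient path, warm-started down the grid."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(np.diff(lam_grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    d = X.shape[1]
    if marker_names is None:
        marker_names = [f"x{j}" for j in range(d)]
    coefs = np.zeros((len(lam_grid), d))
    intercepts = np.zeros(len(lam_grid))
    entry: dict[str, float] = {}
    init = None
    for i, lam in enumerate(lam_grid):
        model = fit_l1_logistic(X, y, lam, marker_names, init=init)
        coefs[i] = model.coef
        intercepts[i] = model.intercept
        init = (model.intercept, model.coef)
        for j, name in enumerate(marker_names):
            if model.coef[j] != 0.0 and name not in entry:
                entry[name] = float(lam)
    return LassoPath(lam_grid, coefs, intercepts, list(marker_names), entry)


def default_lambda_grid(X, y, n_points: int = 30, ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(np.asarray(X, float), np.asarray(y, float))
    return np.geomspace(lmax, lmax * ratio, n_points)


def pca_contribution(X, K: int = 4, marker_names: list[str] | None = None) -> pd.Series:
    """Per-marker PCA contribution c_m = sum_{k<=K} |loading_mk|.

    Loadings are the unit-norm principal-axis entries of the column-centered
    matrix, ordered by decreasing explained variance; the contribution is
    invariant to component sign flips.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if marker_names is None:
        marker_names = [f"x{j}" for j in range(d)]
    n_avail = min(n - 1, d)
    if K > n_avail:
        raise ValueError(f"K = {K} exceeds the {n_avail} available components")
    pca = PCA(n_components=K, svd_solver="full")
    pca.fit(X)
    contrib = np.abs(pca.components_).sum(axis=0)
    return pd.Series(contrib, index=marker_names, name="contribution")


@dataclass
class PrioritizationResult:
    table: pd.DataFrame  # index marker: coefficient, contribution, selected, rank

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def merge_rankings(model: LogisticModel, contributions: pd.Series, q: int = 5) -> PrioritizationResult:
    """Union the L1 support with the top-q PCA contributors.

    Rank is lexicographic: markers with non-zero coefficient first (by
    |coefficient| descending), then the rest by contribution descending; name
    breaks residual ties deterministically.
    """
    names = list(model.marker_names)
    if set(names) != set(contributions.index):
        raise ValueError("model and contributions cover different marker panels")
    if q < 0 or q > len(names):
        raise ValueError(f"q must lie in [0, {len(names)}]")
    coef = pd.Series(model.coef, index=names)
    top_q = set(contributions.sort_values(ascending=False, kind="stable").index[:q])
    selected = {m for m in names if coef[m] != 0.0} | top_q
    order = sorted(
        names,
        key=lambda m: (coef[m] == 0.0, -abs(coef[m]), -contributions[m], m),
    )
    table = pd.DataFrame(
        {
            "coefficient": coef,
            "contribution": contributions.reindex(names),
            "selected": [m in selected for m in names],
            "rank": [order.index(m) + 1 for m in names],
        },
        index=pd.Index(names, name="marker"),
    )
    return PrioritizationResult(table.sort_values("rank"))


# ---------------------------------------------------------------------------
# CV lambda selection and stabilized refit
# ---------------------------------------------------------------------------

def select_lambda_cv(
    X,
    y,
    n_folds: int = 5,
    grid: np.ndarray | None = None,
    seed: int = 0,
    rule: str = "max",
) -> float:
    """Stratified K-fold cross-validated penalty selection on held-out AUROC.

    ``rule='max'`` takes the lambda maximizing the mean fold AUROC (ties
    toward the larger, sparser lambda). ``rule='1se'`` (default) applies the
    one-standard-error convention: the largest lambda whose mean fold AUROC
    is within one standard error of the best — the customary guard against
    over-selection in small cohorts.
    """
    from .stats import fast_auroc as _auroc

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = default_lambda_grid(X, y, n_points=12, ratio=1e-2)
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, ix in enumerate(idx):
            folds[i % n_folds].append(ix)
    fold_scores = np.full((n_folds, len(grid)), np.nan)
    for fi, fold in enumerate(folds):
        fold = np.asarray(fold)
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        if len(np.unique(y[fold])) < 2 or len(np.unique(y[mask])) < 2:
            continue
        init = None
        for gi, lam in enumerate(grid):
            model = fit_l1_logistic(X[mask], y[mask], lam, init=init, tol=1e-6)
            init = (model.intercept, model.coef)
            p = logistic_predict(model, X[fold])
            fold_scores[fi, gi] = _auroc(p, y[fold].astype(int))
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(fold_scores, axis=0)
        n_ok = np.sum(~np.isnan(fold_scores), axis=0)
        sd = np.nanstd(fold_scores, axis=0, ddof=1)
    best = int(np.argmax(mean))  # first (largest lambda) on ties
    if rule == "max":
        return float(grid[best])
    if rule != "1se":
        raise ValueError(f"unknown rule {rule!r}")
    se = sd[best] / math.sqrt(max(n_ok[best], 1))
    ok = np.flatnonzero(mean >= mean[best] - se)
    return float(grid[int(ok[0])])  # largest qualifying lambda


def refit_ridge_logistic(
    X, y, marker_names: list[str], l2: float = 1e-4, tol: float = 1e-10, max_iter: int = 200
) -> LogisticModel:
    """Logistic refit on a selected subset with a small ridge stabilizer.

    Minimizes the mean NLL + (l2/2)||beta||^2 (intercept unpenalized) by
    Newton's method; the stabilizer guards against complete separation in
    small training splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    w = np.zeros(d + 1)
    Xa = np.hstack([np.ones((n, 1)), X])
    pen = np.full(d + 1, l2)
    pen[0] = 0.0
    for it in range(1, max_iter + 1):
        z = Xa @ w
        p = _sigmoid(z)
        g = Xa.T @ (p - y) / n + pen * w
        if np.max(np.abs(g)) < tol:
            return LogisticModel(float(w[0]), w[1:].copy(), 0.0, list(marker_names), it, True)
        wdiag = np.maximum(p * (1 - p), 1e-12)
        H = (Xa.T * wdiag) @ Xa / n + np.diag(pen)
        w = w - np.linalg.solve(H, g)
    return LogisticModel(float(w[0]), w[1:].copy(), 0.0, list(marker_names), max_iter, False)
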