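"""Robustness certification: bootstrap AUROC intervals, Monte Carlo input
perturbation with frozen cut-offs, and repeated random-split stability with
feature-selection frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    LEAKAGE_SAFE,
    PAPER_FAITHFUL,
    CohortTable,
    CohortValidationError,
    impute_stratified_median,
    split_train_test,
    standardize,
)
from .prioritize import fit_l1_logistic, lambda_max, logistic_predict, refit_ridge_logistic
from .scoring import YOUDEN_ON_TOTAL, ScoreModel, build_additive_model, score_cohort
from .stats import auroc, fast_auroc


@dataclass
class BootstrapResult:
    n_boot: int
    mean: float
    ci_low: float
    ci_high: float
    distribution: np.ndarray
    seed: int


def bootstrap_auroc(scores, labels, n_boot: int = 1000, seed: int = 0) -> BootstrapResult:
    """Class-stratified bootstrap of the AUROC with a percentile 95% CI.

    Stratification preserves both class counts in every resample so the AUROC
    is always defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is small for percentile intervals")
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    if len(idx1) == 0 or len(idx0) == 0:
        raise ValueError("both classes must be present")
    dist = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx1, size=len(idx1)), rng.choice(idx0, size=len(idx0))]
        )
        dist[b] = fast_auroc(scores[take], labels[take])
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return BootstrapResult(n_boot, float(dist.mean()), float(lo), float(hi), dist, seed)


@dataclass
class McLevelSummary:
    epsilon: float
    iterations: int
    mean: float
    sd: float
    min: float


UNIFORM = "uniform"
GAUSSIAN = "gaussian"


def mc_perturbation(
    table: CohortTable,
    model: ScoreModel,
    noise_levels=(0.05, 0.10, 0.20),
    iters: int = 500,
    seed: int = 0,
    noise_law: str = UNIFORM,
) -> list[McLevelSummary]:
    """Monte Carlo measurement-noise certification of a frozen score model.

    Per iteration every model-marker value x becomes x * (1 + u) with u drawn
    iid per cell — uniform on [-eps, eps] (default) or a Gaussian with
    sd = eps/2 truncated at +/-eps. Cut-offs and the total-score threshold
    stay frozen; the AUROC of the perturbed total score is recorded.
    """
    rng = np.random.default_rng(seed)
    names = model.marker_names
    X = table.markers[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("table has missing values among model markers; impute first")
    out = []
    for eps in noise_levels:
        if eps < 0 or eps >= 1:
            raise ValueError("noise level must lie in [0, 1)")
        if eps == 0:
            sc = score_cohort(model, table)
            base = auroc(sc["points"], table.label)
            out.append(McLevelSummary(0.0, iters, base, 0.0, base))
            continue
        cuts = np.array([c.cutoff for c in model.cutoffs])
        above = np.array([c.direction == "above_scores_point" for c in model.cutoffs])
        labels = table.label
        aucs = np.empty(iters)
        for it in range(iters):
            if noise_law == UNIFORM:
                u = rng.uniform(-eps, eps, size=X.shape)
            elif noise_law == GAUSSIAN:
                u = np.clip(rng.normal(0.0, eps / 2.0, size=X.shape), -eps, eps)
            else:
                raise ValueError(f"unknown noise law {noise_law!r}")
            xp = X * (1.0 + u)
            pts = np.where(above, xp > cuts, xp < cuts).sum(axis=1)
            aucs[it] = fast_auroc(pts, labels)
        out.append(
            McLevelSummary(float(eps), iters, float(aucs.mean()), float(aucs.std(ddof=1)),
                           float(aucs.min()))
        )
    return out


@dataclass
class SplitsReport:
    n_splits: int
    hybrid_aurocs: np.ndarray
    additive_aurocs: np.ndarray
    selection_frequency: pd.Series
    wilcoxon_p: float
    paired_t_p: float
    base_seed: int
    redraws: int

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, a in (("hybrid", self.hybrid_aurocs), ("additive", self.additive_aurocs)):
            se = a.std(ddof=1) / np.sqrt(len(a))
            rows[name] = {
                "mean": a.mean(),
                "sd": a.std(ddof=1),
                "ci_mean_low": a.mean() - 1.96 * se,
                "ci_mean_high": a.mean() + 1.96 * se,
                "median": np.median(a),
                "iqr_low": np.percentile(a, 25),
                "iqr_high": np.percentile(a, 75),
            }
        return pd.DataFrame(rows).T


def _one_split(
    table: CohortTable,
    seed: int,
    train_fraction: float,
    lambda_fraction: float | None,
    variant: str | None,
) -> tuple[float, float, list[str]]:
    train, test = split_train_test(table, train_fraction, seed=seed, stratified=True)
    train = impute_stratified_median(train, PAPER_FAITHFUL)
    test = impute_stratified_median(test, LEAKAGE_SAFE, reference=train)
    ztrain, stats_ = standardize(train)
    ztest, _ = standardize(test, stats_)

    X = ztrain.markers.to_numpy(dtype=float)
    y = train.label.astype(float)
    names = train.marker_names
    if lambda_fraction is None:
        # the field's default logistic-LASSO strength (C = 1): lam = 1/n
        lam = 1.0 / len(y)
    else:
        lam = lambda_fraction * lambda_max(X, y)
    l1 = fit_l1_logistic(X, y, lam, names, tol=1e-7)
    selected = l1.support()

    # hybrid: ridge-stabilized refit on the selected subset
    if selected:
        cols = [names.index(m) for m in selected]
        refit = refit_ridge_logistic(X[:, cols], y, selected)
        p_test = logistic_predict(refit, ztest.markers.to_numpy(dtype=float)[:, cols])
        hybrid_auc = auroc(p_test, test.label)
    else:
        hybrid_auc = 0.5  # intercept-only model carries no ranking

    # additive: cut-offs + total threshold fully re-derived on the train part;
    # when the panel comes from the per-split selection, scoring directions
    # follow the fitted coefficient signs (a below-cut point for negative ones)
    panel = selected if variant is None else None
    if variant is None and not selected:
        additive_auc = 0.5
    else:
        directions = None
        if panel is not None:
            coef = dict(zip(names, l1.coef))
            directions = {m: ("above_scores_point" if coef[m] > 0 else
                              "below_scores_point") for m in panel}
        model = build_additive_model(
            train, variant or "hybrid_without_afp", YOUDEN_ON_TOTAL,
            panel=panel, directions=directions,
        )
        sc = score_cohort(model, test)
        additive_auc = auroc(sc["points"], test.label)
    return hybrid_auc, additive_auc, selected


def repeated_splits(
    table: CohortTable,
    n_splits: int = 200,
    train_fraction: float = 0.8,
    base_seed: int = 42,
    variant: str | None = None,
    lambda_fraction: float | None = None,
) -> SplitsReport:
    """Repeated random stratified splits with selection and scoring redone
    from scratch on each training part.

    Per split (seed = base_seed + index): impute and standardize on train,
    L1-select at the default penalty lam = 1/n_train (the C = 1 convention of
    standard logistic-LASSO implementations; pass ``lambda_fraction`` to use
    lam = f * lambda_max recomputed per split instead), ridge-refit the
    hybrid model, build the additive model (Youden cut-offs and total
    threshold on train), and evaluate both by AUROC on the untouched test
    part. The additive model is derived from scratch per split: by default
    (``variant=None``) it scores the per-split LASSO selection with
    coefficient-sign-aware directions; a named variant scores that fixed
    panel instead. Degenerate splits are redrawn
    with an incremented sub-seed and counted.
    """
    hybrid = np.empty(n_splits)
    additive = np.empty(n_splits)
    counts = pd.Series(0.0, index=table.marker_names)
    redraws = 0
    for i in range(n_splits):
        seed = base_seed + i
        for attempt in range(20):
            try:
                h, a, sel = _one_split(
                    table, seed + 1_000_003 * attempt, train_fraction, lambda_fraction, variant
                )
                break
            except (CohortValidationError, ValueError):
                redraws += 1
        else:
            raise RuntimeError(f"split {i} failed after 20 redraws")
        hybrid[i] = h
        additive[i] = a
        counts[sel] += 1.0
    diffs = additive - hybrid
    if np.allclose(diffs, 0):
        wp, tp = 1.0, 1.0
    else:
        wp = float(sps.wilcoxon(additive, hybrid, zero_method="wilcox",
                                correction=False, method="approx").pvalue)
        tp = float(sps.ttest_rel(additive, hybrid).pvalue)
    return SplitsReport(
        n_splits, hybrid, additive, counts / n_splits, wp, tp, base_seed, redraws
    )
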