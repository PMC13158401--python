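"""Discrimination and group-comparison statistics.

AUROC is computed by tie-corrected pair counting (probability that a random
iCCA patient outranks a random HCC patient, ties counting one half) and is
identical to the trapezoidal area under the empirical ROC curve; both routes
are exposed so the identity can be asserted. DeLong's method provides the
AUROC standard error and paired model comparisons from placement values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable


class DegenerateInputError(ValueError):
    pass


def _check_binary_both(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise DegenerateInputError("both classes must be present")
    return labels


@dataclass
class RocResult:
    thresholds: np.ndarray  # decreasing; predict positive iff score >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    auroc_trapezoid: float
    max_youden: float


def compute_auroc(scores, labels) -> RocResult:
    """Empirical ROC over all distinct thresholds plus AUROC both ways."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary_both(np.asarray(labels))
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)

    # pair counting with mid-rank ties: AUC = (R1 - n1(n1+1)/2) / (n1 n0)
    ranks = sps.rankdata(scores)
    auc_pairs = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # explicit ROC curve: thresholds at distinct score values, rule score >= t
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc_trap = float(np.trapezoid(sens, fpr))

    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auroc=float(auc_pairs),
        auroc_trapezoid=auc_trap,
        max_youden=float(np.max(sens + spec - 1.0)),
    )


def auroc(scores, labels) -> float:
    return compute_auroc(scores, labels).auroc


def fast_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mid-rank AUROC without building the ROC arrays (resampling loops)."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    # V10_i = fraction of negatives below pos_i (+ half ties)
    order = np.sort(neg)
    below = np.searchsorted(order, pos, side="left")
    ties = np.searchsorted(order, pos, side="right") - below
    v10 = (below + 0.5 * ties) / n0
    order = np.sort(pos)
    below = np.searchsorted(order, neg, side="left")
    ties = np.searchsorted(order, neg, side="right") - below
    v01 = 1.0 - (below + 0.5 * ties) / n1
    return v10, v01


@dataclass
class DeLongResult:
    auroc_a: float
    auroc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    se_a: float
    se_b: float
    degenerate: bool = False


def delong_compare(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong comparison of two AUROCs on the same patients."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary_both(np.asarray(labels))
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("score vectors and labels must have equal length")

    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    n1, n0 = len(v10a), len(v01a)
    auc_a = v10a.mean()
    auc_b = v10b.mean()

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    s = s10 / n1 + s01 / n0
    var_a, var_b, cov_ab = s[0, 0], s[1, 1], s[0, 1]
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff <= 0:
        # identical scores or zero-variance placements: no test possible
        return DeLongResult(
            float(auc_a), float(auc_b), float(var_a), float(var_b), float(cov_ab),
            0.0, 1.0, math.sqrt(max(var_a, 0.0)), math.sqrt(max(var_b, 0.0)),
            degenerate=True,
        )
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(
        float(auc_a), float(auc_b), float(var_a), float(var_b), float(cov_ab),
        float(z), float(p), math.sqrt(max(var_a, 0.0)), math.sqrt(max(var_b, 0.0)),
    )


def delong_se(scores, labels) -> float:
    """One-sample DeLong standard error of the AUROC (for normal CIs)."""
    r = delong_compare(scores, scores, labels)
    return r.se_a


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionReport:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    chi2: float
    p: float


def confusion_metrics(predicted, truth) -> ConfusionReport:
    """2x2 confusion counts with Pearson chi-square (no continuity correction).

    Metrics with an empty margin are reported as None (undefined), never 0.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = _check_binary_both(np.asarray(truth))
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    n = tp + fp + fn + tn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    row1, row0 = tp + fp, fn + tn
    col1, col0 = tp + fn, fp + tn
    if row1 == 0 or row0 == 0 or col1 == 0 or col0 == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = n * (tp * tn - fp * fn) ** 2 / (row1 * row0 * col1 * col0)
        p = float(sps.chi2.sf(chi2, df=1))
    return ConfusionReport(tp, fp, fn, tn, float(sens), float(spec), ppv, npv, float(chi2), p)


# ---------------------------------------------------------------------------
# Univariate marker panel
# ---------------------------------------------------------------------------

def _welch_power(d: float, n0: int, n1: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided Welch test at the observed Cohen's d
    (noncentral-t formulation with the harmonic-mean sample size)."""
    if d == 0:
        return alpha
    nc = abs(d) * math.sqrt(n0 * n1 / (n0 + n1))
    df = n0 + n1 - 2
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def univariate_marker_stats(table: CohortTable) -> pd.DataFrame:
    """Per-marker two-group summary: medians, fold-change, Welch t,
    Mann-Whitney (exact when n <= 10 per group and untied), Cohen's d with
    pooled sd, post-hoc power, and single-marker AUROC.

    Degenerate markers (fewer than 2 observed values in a class) are flagged
    with NaN statistics rather than aborting the panel.
    """
    rows = []
    for spec in table.specs:
        col = table.markers[spec.name]
        x0 = col[table.label == 0].dropna().to_numpy()
        x1 = col[table.label == 1].dropna().to_numpy()
        row: dict = {"marker": spec.name, "units": spec.units, "flagged": False}
        if len(x0) < 2 or len(x1) < 2:
            row.update(
                median_hcc=np.nan, median_icca=np.nan, fold_change=np.nan,
                welch_t=np.nan, welch_p=np.nan, mwu_u=np.nan, mwu_p=np.nan,
                cohens_d=np.nan, power=np.nan, auroc=np.nan, flagged=True,
            )
            rows.append(row)
            continue
        med0, med1 = float(np.median(x0)), float(np.median(x1))
        t, p_t = sps.ttest_ind(x1, x0, equal_var=False)
        exact = len(x0) <= 10 and len(x1) <= 10 and len(np.unique(np.r_[x0, x1])) == len(x0) + len(x1)
        mwu = sps.mannwhitneyu(x1, x0, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
        n0, n1 = len(x0), len(x1)
        sp = math.sqrt(((n0 - 1) * np.var(x0, ddof=1) + (n1 - 1) * np.var(x1, ddof=1))
                       / (n0 + n1 - 2))
        d = 0.0 if sp == 0 else float((np.mean(x1) - np.mean(x0)) / sp)
        labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
        auc = auroc(np.r_[x0, x1], labels)
        row.update(
            median_hcc=med0,
            median_icca=med1,
            fold_change=med1 / med0 if med0 > 0 else np.nan,
            welch_t=float(t),
            welch_p=float(p_t),
            mwu_u=float(mwu.statistic),
            mwu_p=float(mwu.pvalue),
            cohens_d=d,
            power=_welch_power(d, n0, n1),
            auroc=auc,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")
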