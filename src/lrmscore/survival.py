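"""Exploratory overall-survival analysis.

Patients are dichotomized at the within-table marker median (strictly above
vs at-or-below), survival is summarized by Kaplan-Meier product-limit curves
with the median OS read off as the first time S(t) <= 0.5, groups are
compared by the log-rank (Mantel-Cox) test — with the Gehan-Breslow-Wilcoxon
variant, which weights early events by the number at risk, as a sensitivity
analysis — and the hazard ratio comes from a single-binary-covariate Cox
proportional-hazards fit (Breslow tie handling). Estimation is delegated to
lifelines; this module fixes the conventions and the report surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .cohort import CohortTable

LOGRANK = "logrank"
GEHAN = "gehan"


def stratify_by_median(table: CohortTable, marker: str) -> np.ndarray:
    """Binary groups at the within-table median: 1 = strictly above,
    0 = at or below. The median is the conventional mid-point of the order
    statistics. Errors if one group would be empty."""
    if marker not in table.marker_names:
        raise KeyError(f"unknown marker {marker!r}")
    x = table.markers[marker].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"marker {marker!r} has missing values")
    med = float(np.median(x))
    group = (x > med).astype(int)
    if group.min() == group.max():
        raise ValueError(f"all values of {marker!r} fall on one side of the median")
    return group


@dataclass
class SurvivalFit:
    times: np.ndarray  # event times where S drops
    survival: np.ndarray  # S(t) just after each drop
    at_risk: np.ndarray
    median_os: float | None  # None if S never reaches 0.5

    def step_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(times, events) -> SurvivalFit:
    """Kaplan-Meier product-limit estimator for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # restrict to event times (where the curve drops)
    ev_times = np.unique(times[events == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in ev_times])
    at_risk = np.array([int((times >= t).sum()) for t in ev_times])
    med = kmf.median_survival_time_
    median_os = None if math.isinf(med) else float(med)
    return SurvivalFit(ev_times, surv, at_risk, median_os)


@dataclass
class SurvTestResult:
    chi2: float
    p: float
    weights: str
    df: int = 1


def weighted_logrank(times, events, group, weights: str = LOGRANK) -> SurvTestResult:
    """Two-group weighted log-rank test.

    ``logrank`` uses unit weights; ``gehan`` (Gehan-Breslow-Wilcoxon) weights
    each event time by the total number at risk.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    if group.min() == group.max():
        raise ValueError("two non-empty groups required")
    if events.sum() == 0:
        raise ValueError("no events observed")
    if weights == LOGRANK:
        res = _lifelines_logrank(times[group == 0], times[group == 1],
                                 events[group == 0], events[group == 1])
    elif weights == GEHAN:
        res = _lifelines_logrank(times[group == 0], times[group == 1],
                                 events[group == 0], events[group == 1],
                                 weightings="wilcoxon")
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    return SurvTestResult(float(res.test_statistic), float(res.p_value), weights)


@dataclass
class CoxResult:
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    converged: bool
    unbounded: bool = False


def cox_hr_binary(times, events, group) -> CoxResult:
    """Cox proportional-hazards fit for a single binary covariate.

    Breslow tie handling; Wald 95% CI. Monotone-likelihood configurations
    (all events in one group preceding the other's) are flagged unbounded.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    if group.min() == group.max():
        raise ValueError("two non-empty groups required")
    for g in (0, 1):
        if events[group == g].sum() < 1:
            raise ValueError(f"group {g} has no events")
    df = pd.DataFrame({"t": times, "e": events, "g": group})
    cph = CoxPHFitter()
    try:
        with np.errstate(all="ignore"):
            cph.fit(df, duration_col="t", event_col="e", show_progress=False,
                    fit_options={"precision": 1e-9})
    except Exception:
        return CoxResult(math.inf, math.inf, math.inf, 0.0, math.inf, False, unbounded=True)
    log_hr = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    if not math.isfinite(log_hr) or not math.isfinite(se) or se > 50:
        return CoxResult(log_hr, se, math.exp(min(log_hr, 700)), 0.0, math.inf, False, True)
    return CoxResult(
        log_hr,
        se,
        math.exp(log_hr),
        math.exp(log_hr - 1.96 * se),
        math.exp(log_hr + 1.96 * se),
        True,
    )


def logrank_hr_approx(times, events, group) -> float:
    """O/E-ratio hazard-ratio approximation, as survival-curve software
    reports alongside the Cox estimate: HR = (O1/E1) / (O0/E0)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    o = np.array([events[group == g].sum() for g in (0, 1)], dtype=float)
    e = np.zeros(2)
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = float(((times == t) & (events == 1)).sum())
        n_tot = float(at_risk.sum())
        for g in (0, 1):
            e[g] += d * (at_risk & (group == g)).sum() / n_tot
    if o[0] == 0 or e[0] == 0 or e[1] == 0:
        return math.inf
    return float((o[1] / e[1]) / (o[0] / e[0]))


def _km_median(times: np.ndarray, events: np.ndarray) -> float | None:
    """Median OS from a direct product-limit pass (fast path for bootstraps);
    agrees with km_estimate().median_os."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = len(t_sorted)
    s = 1.0
    i = 0
    while i < n:
        t = t_sorted[i]
        j = i
        d = 0
        while j < n and t_sorted[j] == t:
            d += e_sorted[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / (n - i)
            if s <= 0.5:
                return float(t)
        i = j
    return None


@dataclass
class MedianRatioCI:
    ratio: float | None
    ci_low: float | None
    ci_high: float | None
    n_boot: int


def median_ratio_bootstrap(
    times, events, group, n_boot: int = 1000, seed: int = 0
) -> MedianRatioCI:
    """Stratified bootstrap percentile CI for the ratio of group median OS
    (group-0 median / group-1 median, the 'fold-longer survival' of the
    low-marker group). Resamples with undefined medians are skipped."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    rng = np.random.default_rng(seed)

    def ratio_of(idx0: np.ndarray, idx1: np.ndarray) -> float | None:
        m = []
        for idx in (idx0, idx1):
            med = _km_median(times[idx], events[idx])
            if med is None or med == 0:
                return None
            m.append(med)
        return m[0] / m[1]

    i0 = np.flatnonzero(group == 0)
    i1 = np.flatnonzero(group == 1)
    point = ratio_of(i0, i1)
    dist = []
    for _ in range(n_boot):
        r = ratio_of(rng.choice(i0, size=len(i0)), rng.choice(i1, size=len(i1)))
        if r is not None:
            dist.append(r)
    if point is None or len(dist) < max(50, n_boot // 10):
        return MedianRatioCI(point, None, None, n_boot)
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return MedianRatioCI(point, float(lo), float(hi), n_boot)
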