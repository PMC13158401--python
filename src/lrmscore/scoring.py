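"""Additive point-score construction: per-marker ROC-Youden cut-offs, fixed
guideline/PRISM cut-offs, and the total-score classification rule.

The clinical artifact is a paper-and-pencil scorecard: each marker strictly
above its cut-off contributes one point (strictly below, for markers declared
with the opposite direction), and a total of at least T points classifies the
patient as iCCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .markers import (
    ABOVE,
    BELOW,
    AFP_GUIDELINE_CUTOFF,
    HYBRID_PANEL_WITH_AFP,
    HYBRID_PANEL_WITHOUT_AFP,
    PRISM_CUTOFFS,
    PRISM_PANEL,
    MarkerSpec,
)

YOUDEN_ON_TOTAL = "youden_on_total"
FIXED_TEXT_RULE = "fixed_text_rule"
FIXED_RULE_THRESHOLD = 4  # "0-3 points: HCC; 4+ points: iCCA"

VARIANTS = (
    "hybrid_with_afp",
    "hybrid_without_afp",
    "hybrid_fixed_afp",
    "prism",
    "prism_plus_afp",
)


@dataclass(frozen=True)
class CutoffSpec:
    marker: str
    cutoff: float
    source: str  # youden | fixed_guideline | prism_table
    direction: str = ABOVE
    J: float | None = None  # Youden index at derivation


@dataclass
class ScoreModel:
    variant: str
    cutoffs: list[CutoffSpec]
    threshold: int
    threshold_source: str

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= len(self.cutoffs):
            raise ValueError("threshold must lie in [1, number of cutoffs]")

    @property
    def marker_names(self) -> list[str]:
        return [c.marker for c in self.cutoffs]

    def to_json(self, path=None) -> str:
        payload = {
            "variant": self.variant,
            "threshold": self.threshold,
            "threshold_source": self.threshold_source,
            "cutoffs": [asdict(c) for c in self.cutoffs],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def scorecard(self, units: dict[str, str] | None = None) -> str:
        """Human-readable scorecard block."""
        units = units or {}
        lines = [f"Additive score ({self.variant})", "-" * 40]
        for c in self.cutoffs:
            side = "above" if c.direction == ABOVE else "below"
            u = f" {units[c.marker]}" if c.marker in units else ""
            lines.append(f"  {c.marker}: 1 point if {side} {c.cutoff:g}{u}")
        lines.append(f"  total >= {self.threshold}  ->  iCCA, else HCC")
        return "\n".join(lines)


def youden_cutoff(values, labels, direction: str = ABOVE) -> CutoffSpec:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values plus -inf/+inf sentinels (the "nobody scores" / "everybody scores"
    classifiers); sensitivity counts class-1 patients on the scoring side of
    the cut (strictly above for ``above_scores_point``). Ties on J break
    toward higher specificity, then lower threshold. A winning sentinel is
    materialized as the nearest observed extreme (e.g. the maximum value for
    +inf under the strictly-above rule), which leaves sensitivity and
    specificity on the derivation data unchanged while keeping the cut-off
    finite.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.isnan(values).any():
        raise ValueError("values contain missing entries; impute first")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    if len(uniq) == 1:
        raise ValueError("all values identical; Youden cut-off undefined")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = values[labels == 1]
    neg = values[labels == 0]
    best = None
    for c in candidates:
        if direction == ABOVE:
            sens = float((pos > c).mean())
            spec = float((neg <= c).mean())
        else:
            sens = float((pos < c).mean())
            spec = float((neg >= c).mean())
        j = sens + spec - 1.0
        key = (round(j, 15), round(spec, 15), -c)  # J desc, spec desc, cutoff asc
        if best is None or key > best[0]:
            best = (key, c, j)
    _, cut, j = best
    if cut == np.inf:
        cut = uniq[-1] if direction == ABOVE else uniq[-1] + (uniq[-1] - uniq[0])
    elif cut == -np.inf:
        cut = uniq[0] - (uniq[-1] - uniq[0]) if direction == ABOVE else uniq[0]
    return CutoffSpec(marker="", cutoff=float(cut), source="youden", direction=direction, J=float(j))


def _youden_total_threshold(points: np.ndarray, labels: np.ndarray) -> int:
    """Youden-optimal integer T for the rule 'iCCA iff total >= T'.

    Ties break toward higher specificity (larger T), then lower T among equal
    (sens, spec) — i.e. first by J, then spec, then smaller T.
    """
    pos = points[labels == 1]
    neg = points[labels == 0]
    best = None
    for t in range(1, int(points.max()) + 2):
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        key = (round(j, 15), round(spec, 15), -t)
        if best is None or key > best[0]:
            best = (key, t)
    return int(best[1])


def _panel_for_variant(variant: str) -> list[str]:
    if variant in ("hybrid_with_afp", "hybrid_fixed_afp"):
        return list(HYBRID_PANEL_WITH_AFP)
    if variant == "hybrid_without_afp":
        return list(HYBRID_PANEL_WITHOUT_AFP)
    if variant == "prism":
        return list(PRISM_PANEL)
    if variant == "prism_plus_afp":
        return ["afp_ng_ml"] + list(PRISM_PANEL)
    raise ValueError(f"unknown variant {variant!r}")


def build_additive_model(
    train: CohortTable | None,
    variant: str,
    threshold_source: str = YOUDEN_ON_TOTAL,
    panel: list[str] | None = None,
    directions: dict[str, str] | None = None,
) -> ScoreModel:
    """Assemble a ScoreModel for one variant.

    Hybrid variants derive per-marker cut-offs by Youden on the (imputed,
    native-unit) training split — except AFP, fixed at 20 ng/ml under
    ``hybrid_fixed_afp``. PRISM variants use the fixed published constants and
    need no training data unless T is re-derived by ``youden_on_total``.
    ``panel`` overrides the variant's default marker list (e.g. a per-split
    LASSO selection) and ``directions`` overrides per-marker scoring
    directions (e.g. sign-aware translation of fitted coefficients); both
    default to the MarkerSpec declarations (every marker scoring above its
    cut-off, the literal published rule).
    """
    markers = panel if panel is not None else _panel_for_variant(variant)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    spec_dirs = {s.name: s.score_direction for s in (train.specs if train else [])}
    if directions:
        spec_dirs.update(directions)

    cutoffs: list[CutoffSpec] = []
    for m in markers:
        direction = spec_dirs.get(m, ABOVE)
        if variant in ("prism", "prism_plus_afp") and m in PRISM_CUTOFFS:
            cutoffs.append(CutoffSpec(m, PRISM_CUTOFFS[m], "prism_table", direction))
        elif m == "afp_ng_ml" and variant in ("hybrid_fixed_afp", "prism_plus_afp"):
            cutoffs.append(CutoffSpec(m, AFP_GUIDELINE_CUTOFF, "fixed_guideline", direction))
        else:
            if train is None:
                raise ValueError(f"variant {variant!r} needs training data for marker {m!r}")
            col = train.markers[m].to_numpy(dtype=float)
            spec = youden_cutoff(col, train.label, direction)
            cutoffs.append(CutoffSpec(m, spec.cutoff, "youden", direction, spec.J))

    if threshold_source == FIXED_TEXT_RULE:
        threshold = min(FIXED_RULE_THRESHOLD, len(cutoffs))
    elif threshold_source == YOUDEN_ON_TOTAL:
        if train is None:
            raise ValueError("youden_on_total threshold needs training data")
        pts = _points(cutoffs, train.markers)
        threshold = _youden_total_threshold(pts, train.label)
    else:
        raise ValueError(f"unknown threshold_source {threshold_source!r}")
    return ScoreModel(variant, cutoffs, threshold, threshold_source)


def _points(cutoffs: list[CutoffSpec], markers: pd.DataFrame) -> np.ndarray:
    pts = np.zeros(len(markers), dtype=int)
    for c in cutoffs:
        if c.marker not in markers.columns:
            raise ValueError(f"marker {c.marker!r} absent from table")
        x = markers[c.marker].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"missing values in marker {c.marker!r}; impute first")
        if c.direction == ABOVE:
            pts += (x > c.cutoff).astype(int)
        else:
            pts += (x < c.cutoff).astype(int)
    return pts


def score_cohort(model: ScoreModel, table: CohortTable) -> pd.DataFrame:
    """Per-patient points and predicted class (iCCA iff points >= T)."""
    pts = _points(model.cutoffs, table.markers)
    pred = (pts >= model.threshold).astype(int)
    return pd.DataFrame(
        {
            "patient_id": np.asarray(table.patient_id),
            "label": table.label,
            "points": pts,
            "predicted": pred,
            "predicted_class": np.where(pred == 1, "iCCA", "HCC"),
        }
    )
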