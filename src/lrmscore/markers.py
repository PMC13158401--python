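"""Marker panel definitions for the LR-M HCC-vs-iCCA cohort.

The panel combines six routine serological markers with three CD133/2-positive
small-EV subpopulations quantified by single-particle interferometry
(particles/ml). Serology may carry sparse, non-systematic missingness; EV
columns are required to be complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


ABOVE = "above_scores_point"
BELOW = "below_scores_point"


@dataclass(frozen=True)
class MarkerSpec:
    """Declaration of a single biomarker column.

    ``score_direction`` states which side of a cut-off contributes a point in
    an additive score: ``above_scores_point`` means strictly greater values
    score (the default for every marker, including AFP, following the literal
    additive rule).
    """

    name: str
    units: str
    marker_class: str  # "serology" | "ev"
    score_direction: str = ABOVE
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.marker_class not in ("serology", "ev"):
            raise ValueError(f"unknown marker_class {self.marker_class!r}")
        if self.score_direction not in (ABOVE, BELOW):
            raise ValueError(f"unknown score_direction {self.score_direction!r}")
        if self.marker_class == "ev" and self.allow_missing:
            raise ValueError(f"EV marker {self.name!r} must not allow missing values")


def default_panel() -> list[MarkerSpec]:
    """The nine-marker study panel in canonical column order."""
    return [
        MarkerSpec("afp_ng_ml", "ng/ml", "serology", allow_missing=True),
        MarkerSpec("albumin", "g/dl", "serology", allow_missing=True),
        MarkerSpec("alp_u_l", "U/L", "serology", allow_missing=True),
        MarkerSpec("ca19_9_u_ml", "U/ml", "serology", allow_missing=True),
        MarkerSpec("crp", "mg/dl", "serology", allow_missing=True),
        MarkerSpec("thrombocytes_e3_ul", "10^3/ul", "serology", allow_missing=True),
        MarkerSpec("cd9_cd133_2_per_ml", "particles/ml", "ev"),
        MarkerSpec("cd63_cd133_2_per_ml", "particles/ml", "ev"),
        MarkerSpec("cd81_cd133_2_per_ml", "particles/ml", "ev"),
    ]


MARKER_NAMES: tuple[str, ...] = tuple(m.name for m in default_panel())

# Score-model panels. Hybrid panels derive cut-offs from data (ROC-Youden);
# PRISM panels use fixed published constants.
HYBRID_PANEL_WITH_AFP: tuple[str, ...] = (
    "afp_ng_ml",
    "ca19_9_u_ml",
    "crp",
    "alp_u_l",
    "cd9_cd133_2_per_ml",
    "cd81_cd133_2_per_ml",
)
HYBRID_PANEL_WITHOUT_AFP: tuple[str, ...] = HYBRID_PANEL_WITH_AFP[1:]
PRISM_PANEL: tuple[str, ...] = (
    "alp_u_l",
    "ca19_9_u_ml",
    "crp",
    "cd9_cd133_2_per_ml",
    "cd81_cd133_2_per_ml",
)

# Fixed PRISM cut-offs (single-marker ROC analyses, shipped as the default
# PRISM preset) and the guideline AFP threshold.
PRISM_CUTOFFS: dict[str, float] = {
    "alp_u_l": 439.0,
    "ca19_9_u_ml": 16.3,
    "crp": 0.87,
    "cd9_cd133_2_per_ml": 3.2e6,
    "cd81_cd133_2_per_ml": 1.06e6,
}
AFP_GUIDELINE_CUTOFF = 20.0

# Published ROC-Youden cut-offs of the two hybrid variants, shipped verbatim
# as named presets (the CA19-9 value differs slightly between variants).
HYBRID_YOUDEN_PRESET_WITH_AFP: dict[str, float] = {
    "afp_ng_ml": 400.0,
    "alp_u_l": 456.0,
    "ca19_9_u_ml": 117.0,
    "crp": 0.88,
    "cd9_cd133_2_per_ml": 5.292e6,
    "cd81_cd133_2_per_ml": 2.45055e6,
}
HYBRID_YOUDEN_PRESET_WITHOUT_AFP: dict[str, float] = {
    k: v for k, v in HYBRID_YOUDEN_PRESET_WITH_AFP.items() if k != "afp_ng_ml"
}
HYBRID_YOUDEN_PRESET_WITHOUT_AFP["ca19_9_u_ml"] = 117.9


def panel_by_name(names: Iterable[str]) -> list[MarkerSpec]:
    """Subset the default panel, preserving canonical order of ``names``."""
    lookup = {m.name: m for m in default_panel()}
    out = []
    for n in names:
        if n not in lookup:
            raise KeyError(f"unknown marker {n!r}")
        out.append(lookup[n])
    return out
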