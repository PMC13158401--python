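"""Cohort table IO, validation, standardization, imputation and splitting.

A cohort is a per-patient table: binary diagnosis label (0 = HCC, 1 = iCCA),
a marker matrix in native units, and optional overall-survival columns
(``os_days`` and ``event``, 1 = death). The CSV dialect is UTF-8,
comma-separated, header row, empty cell = missing, decimal point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerSpec, default_panel

PAPER_FAITHFUL = "paper_faithful"
LEAKAGE_SAFE = "leakage_safe"


class CohortFormatError(ValueError):
    """Raised when the file layout does not match the declared marker panel."""


class CohortValidationError(ValueError):
    """Raised when values violate cohort invariants (negatives, EV gaps...)."""


@dataclass
class CohortTable:
    """Validated per-patient cohort.

    ``markers`` is a patients x markers DataFrame of non-negative reals in
    native units (NaN = missing, permitted only where the spec allows).
    """

    patient_id: pd.Index
    label: np.ndarray
    markers: pd.DataFrame
    specs: list[MarkerSpec]
    os_days: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        if not set(np.unique(self.label)) <= {0, 1}:
            raise CohortValidationError("label must be binary (0 = HCC, 1 = iCCA)")
        if len(self.patient_id) != len(self.label) or len(self.markers) != len(self.label):
            raise CohortValidationError("patient_id, label and markers disagree in length")
        spec_names = [s.name for s in self.specs]
        if list(self.markers.columns) != spec_names:
            raise CohortFormatError(
                f"marker columns {list(self.markers.columns)} do not match specs {spec_names}"
            )
        if (self.os_days is None) != (self.event is None):
            raise CohortValidationError("os_days and event must be given together")
        if self.os_days is not None:
            self.os_days = np.asarray(self.os_days, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if np.any(self.os_days < 0):
                raise CohortValidationError("os_days must be non-negative")
            if not set(np.unique(self.event)) <= {0, 1}:
                raise CohortValidationError("event must be binary")
        self._validate_markers()

    def _validate_markers(self) -> None:
        for spec in self.specs:
            col = self.markers[spec.name]
            # z-scored tables (units == "z") are signed by construction
            if spec.units != "z" and (col.dropna() < 0).any():
                raise CohortValidationError(f"negative value in marker {spec.name!r}")
            if not spec.allow_missing and col.isna().any():
                raise CohortValidationError(
                    f"missing entry in marker {spec.name!r} which does not allow missing"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.label)

    @property
    def marker_names(self) -> list[str]:
        return list(self.markers.columns)

    @property
    def has_survival(self) -> bool:
        return self.os_days is not None

    def subset(self, idx: np.ndarray) -> "CohortTable":
        """Row subset by positional indices, preserving order of ``idx``."""
        idx = np.asarray(idx)
        return CohortTable(
            patient_id=self.patient_id[idx],
            label=self.label[idx],
            markers=self.markers.iloc[idx].reset_index(drop=True),
            specs=list(self.specs),
            os_days=None if self.os_days is None else self.os_days[idx],
            event=None if self.event is None else self.event[idx],
        )

    def class_mask(self, cls: int) -> np.ndarray:
        return self.label == cls

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_id, "label": self.label})
        df = pd.concat([df, self.markers.reset_index(drop=True)], axis=1)
        if self.os_days is not None:
            df["os_days"] = self.os_days
            df["event"] = self.event
        return df


@dataclass(frozen=True)
class StandardizationStats:
    """Per-marker mean/sd fitted on a stated reference set (sample sd, n-1)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any() or self.sd.isna().any():
            bad = list(self.sd.index[(self.sd <= 0) | self.sd.isna()])
            raise CohortValidationError(f"non-positive standard deviation for markers {bad}")


def read_cohort(path, specs: list[MarkerSpec] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Header must contain ``patient_id``, ``label``, every spec'd marker, and
    optionally ``os_days``/``event``. Empty cells become missing values; row
    order is preserved.
    """
    specs = list(specs) if specs is not None else default_panel()
    df = pd.read_csv(path)
    required = ["patient_id", "label"] + [s.name for s in specs]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"missing columns: {missing_cols}")
    known = set(required) | {"os_days", "event"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise CohortFormatError(f"unknown columns: {unknown}")
    has_os = "os_days" in df.columns
    has_event = "event" in df.columns
    if has_os != has_event:
        raise CohortFormatError("os_days and event must both be present or both absent")
    return CohortTable(
        patient_id=pd.Index(df["patient_id"]),
        label=df["label"].to_numpy(),
        markers=df[[s.name for s in specs]].astype(float),
        specs=specs,
        os_days=df["os_days"].to_numpy(dtype=float) if has_os else None,
        event=df["event"].to_numpy() if has_event else None,
    )


def write_cohort(table: CohortTable, path) -> None:
    """Write the cohort CSV (full float precision, empty cell = missing)."""
    table.to_frame().to_csv(path, index=False, na_rep="")


def standardize(
    table: CohortTable, stats: StandardizationStats | None = None
) -> tuple[CohortTable, StandardizationStats]:
    """Z-score the marker matrix.

    If ``stats`` is absent, mean and sample sd (n-1 denominator) are fitted on
    this table per marker, ignoring missing entries; otherwise the supplied
    stats are applied unchanged (the train-fitted stats applied to a test
    split). Returns the transformed table and the stats actually applied.
    """
    if stats is None:
        mean = table.markers.mean(skipna=True)
        sd = table.markers.std(ddof=1, skipna=True)
        if (sd.isna() | (sd <= 0)).any():
            bad = list(sd.index[sd.isna() | (sd <= 0)])
            raise CohortValidationError(f"zero-variance marker(s) on fitting set: {bad}")
        stats = StandardizationStats(mean=mean, sd=sd)
    z = (table.markers - stats.mean) / stats.sd
    out = CohortTable(
        patient_id=table.patient_id,
        label=table.label,
        markers=z,
        specs=[
            # z-units may be negative and EV completeness still holds
            MarkerSpec(s.name, "z", s.marker_class, s.score_direction,
                       allow_missing=s.marker_class != "ev")
            for s in table.specs
        ],
        os_days=table.os_days,
        event=table.event,
    )
    return out, stats


def impute_stratified_median(
    table: CohortTable,
    mode: str = PAPER_FAITHFUL,
    reference: CohortTable | None = None,
) -> CohortTable:
    """Fill missing serology values by median imputation.

    ``paper_faithful`` replaces a missing value with the median of that marker
    within the patient's own diagnosis class (uses labels; appropriate for
    training data). ``leakage_safe`` replaces it with the overall median of
    the ``reference`` (training) table, so labels are never consulted at
    prediction time.
    """
    if mode not in (PAPER_FAITHFUL, LEAKAGE_SAFE):
        raise ValueError(f"unknown imputation mode {mode!r}")
    markers = table.markers.copy()
    if not markers.isna().any().any():
        return table
    if mode == LEAKAGE_SAFE:
        if reference is None:
            raise ValueError("leakage_safe imputation requires a reference (training) table")
        med = reference.markers.median(skipna=True)
        for name in markers.columns:
            if markers[name].isna().any():
                if np.isnan(med[name]):
                    raise CohortValidationError(
                        f"no observed reference values for marker {name!r}"
                    )
                markers[name] = markers[name].fillna(med[name])
    else:
        for cls in (0, 1):
            mask = table.label == cls
            sub = markers.loc[mask]
            med = sub.median(skipna=True)
            for name in markers.columns:
                if sub[name].isna().any():
                    if np.isnan(med[name]):
                        raise CohortValidationError(
                            f"class {cls} has no observed values for marker {name!r}"
                        )
                    markers.loc[mask, name] = sub[name].fillna(med[name])
    return CohortTable(
        patient_id=table.patient_id,
        label=table.label,
        markers=markers,
        specs=list(table.specs),
        os_days=table.os_days,
        event=table.event,
    )


def split_train_test(
    table: CohortTable,
    train_fraction: float = 0.8,
    seed: int = 42,
    stratified: bool = True,
) -> tuple[CohortTable, CohortTable]:
    """Random disjoint, exhaustive train/test partition.

    Stratified (the default) preserves class proportions to rounding and
    errors if either part would receive zero members of a class. Identical
    seed gives the identical partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n
    if stratified:
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for cls in (0, 1):
            idx = np.flatnonzero(table.label == cls)
            if len(idx) < 2:
                raise CohortValidationError(f"class {cls} has fewer than 2 members")
            n_train = int(round(train_fraction * len(idx)))
            if n_train == 0 or n_train == len(idx):
                raise CohortValidationError(
                    f"stratified split leaves class {cls} empty in one part"
                )
            perm = rng.permutation(idx)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        tr = np.sort(np.concatenate(train_idx))
        te = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        if n_train == 0 or n_train == n:
            raise CohortValidationError("split leaves one part empty")
        tr = np.sort(perm[:n_train])
        te = np.sort(perm[n_train:])
    return table.subset(tr), table.subset(te)
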