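"""Two-visit cephalometric cohort model and the raw-to-difference transform.

The unit of analysis is a patient observed at two visits (ages ``age_t1`` <
``age_t2``), with six craniofacial measurements at each visit: the angles
ANB, IMPA, PPPM (degrees) and the lengths CoA, GoPg, CoGo (millimetres).
Each patient also carries a binary ``treated`` flag and, for untreated
patients, a binary ``growth`` prognosis ("good grower" = 1).  The network
analysis operates not on the raw values but on per-patient differences
(dY = Y_t2 - Y_t1 and dT = age_t2 - age_t1), assembled here into a
:class:`RateTable`.

An optional "adjusted" variant subtracts age-matched normative values from a
reference atlas (linear interpolation between tabulated ages) before the
differences are taken, so that the network describes deviations from normal
growth rather than growth itself.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, CoverageError, FormatError

#: Canonical craniofacial feature names, in fixed column order.
FEATURES = ("ANB", "IMPA", "PPPM", "CoA", "GoPg", "CoGo")

#: Fixed column layout of a :class:`RateTable`.
DELTA_COLUMNS = (
    "dT",
    "Treatment",
    "Growth",
    "dANB",
    "dIMPA",
    "dPPPM",
    "dCoA",
    "dGoPg",
    "dCoGo",
)

#: Difference columns corresponding to the six features, in layout order.
DELTA_FEATURES = ("dANB", "dIMPA", "dPPPM", "dCoA", "dGoPg", "dCoGo")

EXOGENOUS_COLUMNS = ("dT", "Treatment")
OUTCOME_COLUMNS = ("Growth",)


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """A single patient's two-visit record.

    ``growth`` may be ``None`` only for treated patients (the prognosis is
    recorded for untreated subjects; downstream stages state their own
    missing-data policy).
    """

    patient_id: str
    treated: int
    growth: Optional[int]
    age_t1: float
    age_t2: float
    values_t1: Mapping[str, float]
    values_t2: Mapping[str, float]

    def __post_init__(self):
        problems = self.problems()
        if problems:
            raise CohortValidationError([(self.patient_id, p) for p in problems])

    def problems(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out = []
        if self.treated not in (0, 1):
            out.append(f"treated must be 0/1, got {self.treated!r}")
        if self.growth is not None and self.growth not in (0, 1):
            out.append(f"growth must be 0/1 or missing, got {self.growth!r}")
        if self.growth is None and self.treated == 0:
            out.append("growth missing for an untreated patient")
        if not (self.age_t1 > 0 and self.age_t2 > 0):
            out.append("ages must be positive")
        if not self.age_t2 > self.age_t1:
            out.append(f"age_t2 ({self.age_t2}) must exceed age_t1 ({self.age_t1})")
        for name, values in (("values_t1", self.values_t1), ("values_t2", self.values_t2)):
            missing = [f for f in FEATURES if f not in values]
            if missing:
                out.append(f"{name} lacks features {missing}")
        return out


@dataclasses.dataclass(frozen=True)
class Cohort:
    """An ordered, non-empty collection of unique patients."""

    records: tuple[PatientRecord, ...]
    provenance: str = "raw"

    def __post_init__(self):
        if not self.records:
            raise CohortValidationError([("<cohort>", "cohort is empty")])
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError([(d, "duplicate patient_id") for d in dupes])

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-patient layout (the CSV dialect of this package)."""
        rows = []
        for r in self.records:
            row = {
                "id": r.patient_id,
                "treated": r.treated,
                "growth": r.growth,
                "age_t1": r.age_t1,
                "age_t2": r.age_t2,
            }
            for f in FEATURES:
                row[f"{f}_t1"] = r.values_t1[f]
                row[f"{f}_t2"] = r.values_t2[f]
            rows.append(row)
        return pd.DataFrame(rows)


class RateTable:
    """Node-ready difference variables, one row per patient.

    Columns follow :data:`DELTA_COLUMNS`; extra columns (synthetic or derived
    features) may follow the canonical nine and are treated as features by the
    constraint machinery.  The underlying :class:`pandas.DataFrame` is indexed
    by patient id; missing Growth is stored as NaN.
    """

    def __init__(self, frame: pd.DataFrame):
        cols = list(frame.columns)
        if cols[: len(DELTA_COLUMNS)] != list(DELTA_COLUMNS):
            raise FormatError(
                f"rate table must start with columns {list(DELTA_COLUMNS)}, got {cols}"
            )
        if not (frame["dT"] > 0).all():
            bad = frame.index[~(frame["dT"] > 0)].tolist()
            raise CohortValidationError([(str(i), "dT must be positive") for i in bad])
        for col in ("Treatment",):
            if not frame[col].isin([0, 1]).all():
                raise FormatError(f"{col} must be coded 0/1")
        growth = frame["Growth"]
        if not growth.dropna().isin([0, 1]).all():
            raise FormatError("Growth must be coded 0/1 or NaN")
        self.frame = frame.astype(float)

    # -- conveniences -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def feature_columns(self) -> list[str]:
        """Delta features plus any extra appended columns."""
        return list(DELTA_FEATURES) + list(self.frame.columns[len(DELTA_COLUMNS) :])

    def with_column(self, name: str, values: Sequence[float]) -> "RateTable":
        """Return a new table with an extra feature column appended."""
        frame = self.frame.copy()
        frame[name] = np.asarray(values, dtype=float)
        return RateTable(frame)

    def subset(self, mask) -> "RateTable":
        return RateTable(self.frame.loc[mask])


class ReferenceTable:
    """Normative (feature, age) -> value atlas with linear age interpolation.

    Ages must be strictly increasing per feature, with at least two distinct
    ages; evaluation outside the tabulated range is a :class:`CoverageError`
    (atlas tables are sparse and monotone trends are not guaranteed, so
    extrapolation is refused rather than clamped).
    """

    def __init__(self, entries: Mapping[str, tuple[Sequence[float], Sequence[float]]]):
        self._entries: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for feature in FEATURES:
            if feature not in entries:
                raise FormatError(f"reference table lacks feature {feature!r}")
            ages, values = entries[feature]
            ages = np.asarray(ages, dtype=float)
            values = np.asarray(values, dtype=float)
            if len(ages) < 2 or np.any(np.diff(ages) <= 0):
                raise FormatError(
                    f"reference ages for {feature!r} must be >= 2 strictly increasing values"
                )
            self._entries[feature] = (ages, values)

    def lookup(self, feature: str, age: float) -> float:
        ages, values = self._entries[feature]
        if age < ages[0] or age > ages[-1]:
            raise CoverageError(
                f"age {age} outside reference range [{ages[0]}, {ages[-1]}] for {feature}"
            )
        return float(np.interp(age, ages, values))

    @classmethod
    def read(cls, path) -> "ReferenceTable":
        """Read a (feature, age, value) CSV."""
        frame = pd.read_csv(path)
        for col in ("feature", "age", "value"):
            if col not in frame.columns:
                raise FormatError(f"reference CSV lacks column {col!r}")
        entries = {}
        for feature, grp in frame.groupby("feature"):
            grp = grp.sort_values("age")
            entries[str(feature)] = (grp["age"].to_numpy(), grp["value"].to_numpy())
        return cls(entries)

    def write(self, path) -> None:
        rows = [
            {"feature": f, "age": a, "value": v}
            for f, (ages, values) in self._entries.items()
            for a, v in zip(ages, values)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    ["id", "treated", "growth", "age_t1", "age_t2"]
    + [f"{f}_t1" for f in FEATURES]
    + [f"{f}_t2" for f in FEATURES]
)


def read_cohort(path, dialect: Optional[Mapping[str, str]] = None,
                visits: str = "strict") -> Cohort:
    """Read a one-row-per-patient cohort CSV.

    Parameters
    ----------
    path : path-like
        CSV with header columns ``id, treated, growth, age_t1, age_t2,
        ANB_t1..CoGo_t1, ANB_t2..CoGo_t2``.  Missing growth is an empty field.
    dialect : mapping, optional
        Maps *file* column names to the canonical names above.
    visits : {"strict", "first_last"}
        ``"strict"`` (default) rejects duplicate patient ids.  With
        ``"first_last"``, multiple rows per patient (extra visits encoded as
        extra rows) are collapsed to the earliest first visit and the latest
        second visit, matching the one-difference-per-patient model.
    """
    frame = pd.read_csv(path)
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"cohort CSV missing column(s): {', '.join(missing)}")

    if visits == "first_last" and frame["id"].duplicated().any():
        frame = _collapse_visits(frame)

    records, diagnostics = [], []
    for _, row in frame.iterrows():
        pid = str(row["id"])
        growth = row["growth"]
        growth = None if pd.isna(growth) else int(growth)
        try:
            rec = PatientRecord(
                patient_id=pid,
                treated=int(row["treated"]),
                growth=growth,
                age_t1=float(row["age_t1"]),
                age_t2=float(row["age_t2"]),
                values_t1={f: float(row[f"{f}_t1"]) for f in FEATURES},
                values_t2={f: float(row[f"{f}_t2"]) for f in FEATURES},
            )
        except CohortValidationError as err:
            diagnostics.extend(err.diagnostics)
            continue
        records.append(rec)
    if diagnostics:
        raise CohortValidationError(diagnostics)
    return Cohort(tuple(records))


def _collapse_visits(frame: pd.DataFrame) -> pd.DataFrame:
    keep = []
    for _, grp in frame.groupby("id", sort=False):
        first = grp.loc[grp["age_t1"].idxmin()]
        last = grp.loc[grp["age_t2"].idxmax()]
        row = first.copy()
        row["age_t2"] = last["age_t2"]
        for f in FEATURES:
            row[f"{f}_t2"] = last[f"{f}_t2"]
        keep.append(row)
    return pd.DataFrame(keep).reset_index(drop=True)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort in the same CSV dialect :func:`read_cohort` reads."""
    cohort.to_frame().to_csv(path, index=False)


def compute_differences(cohort: Cohort) -> RateTable:
    """Per-patient differences dY = Y_t2 - Y_t1 and dT = age_t2 - age_t1."""
    rows = {}
    for r in cohort.records:
        row = {
            "dT": r.age_t2 - r.age_t1,
            "Treatment": float(r.treated),
            "Growth": np.nan if r.growth is None else float(r.growth),
        }
        for f in FEATURES:
            row[f"d{f}"] = r.values_t2[f] - r.values_t1[f]
        rows[r.patient_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(DELTA_COLUMNS)]
    return RateTable(frame)


def adjust_by_reference(cohort: Cohort, reference: ReferenceTable) -> Cohort:
    """Subtract age-matched atlas values from every visit measurement."""
    records = []
    for r in cohort.records:
        try:
            v1 = {f: r.values_t1[f] - reference.lookup(f, r.age_t1) for f in FEATURES}
            v2 = {f: r.values_t2[f] - reference.lookup(f, r.age_t2) for f in FEATURES}
        except CoverageError as err:
            raise CoverageError(f"patient {r.patient_id}: {err}") from err
        records.append(dataclasses.replace(r, values_t1=v1, values_t2=v2))
    return Cohort(tuple(records), provenance="adjusted")
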