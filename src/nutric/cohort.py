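"""Patient-level data model and delimited-text cohort I/O.

A cohort is a list of :class:`PatientRecord`. On disk it is a UTF-8 CSV
with a header row; the per-day energy intake list is serialised in a
single column as ``;``-joined kcal values. Missing optional values are
empty fields (or a configurable sentinel token), never ``0`` — zero is a
real measurement for several of these variables.

Column dictionary (default schema)
----------------------------------
patient_id              opaque identifier
age                     years, >= 18
apache2                 APACHE II score at ICU admission, integer >= 0
sofa                    SOFA score at ICU admission, integer >= 0
days_hosp_to_icu        days from hospital to ICU admission, fractional allowed
bmi                     kg/m^2, > 0, optional
n_comorbid              number of comorbidities, integer 0..5
il6                     interleukin-6, pg/mL, > 0, optional
crp                     C-reactive protein, mg/L, > 0, optional
pct                     procalcitonin, ng/mL, > 0, optional
oral_intake_pct         % oral intake in the prior week, 0..100, optional
weight_loss_pct         % weight loss in the last 3 months, >= 0, optional
mort28                  1 = dead by day 28
mv_start_within_48h     1 = mechanical ventilation started within 48 h
mv_days                 days on mechanical ventilation, 0..28
icu_days                ICU length of stay in days, >= 0
energy_prescribed       prescribed energy, kcal/day, > 0
energy_received_daily   ';'-joined kcal received per ICU day, up to 14 entries
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "COLUMNS",
    "OPTIONAL_FIELDS",
    "CohortError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "compute_vfd",
]

#: Canonical column order for cohort files.
COLUMNS = [
    "patient_id",
    "age",
    "apache2",
    "sofa",
    "days_hosp_to_icu",
    "bmi",
    "n_comorbid",
    "il6",
    "crp",
    "pct",
    "oral_intake_pct",
    "weight_loss_pct",
    "mort28",
    "mv_start_within_48h",
    "mv_days",
    "icu_days",
    "energy_prescribed",
    "energy_received_daily",
]

#: Fields where missingness is meaningful and must stay distinct from zero.
OPTIONAL_FIELDS = frozenset(
    {"bmi", "il6", "crp", "pct", "oral_intake_pct", "weight_loss_pct"}
)

_INT_FIELDS = ("apache2", "sofa", "n_comorbid", "mort28", "mv_start_within_48h")


class CohortError(ValueError):
    """A record violates a hard invariant of the data model."""


class SchemaError(CohortError):
    """A cohort file is missing required columns or has unparseable values."""


@dataclass
class PatientRecord:
    """One patient's predictors, outcomes and daily nutrition intake."""

    patient_id: str
    age: float
    apache2: int
    sofa: int
    days_hosp_to_icu: float
    n_comorbid: int
    mort28: int
    mv_start_within_48h: int
    mv_days: float
    icu_days: float
    energy_prescribed: float
    energy_received_daily: list[float] = field(default_factory=list)
    bmi: float | None = None
    il6: float | None = None
    crp: float | None = None
    pct: float | None = None
    oral_intake_pct: float | None = None
    weight_loss_pct: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.age < 18:
            raise CohortError(f"age must be >= 18, got {self.age}")
        for name in ("apache2", "sofa"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise CohortError(f"{name} must be a non-negative integer, got {v}")
        if self.n_comorbid != int(self.n_comorbid) or not 0 <= self.n_comorbid <= 5:
            raise CohortError(
                f"n_comorbid must be an integer in 0..5, got {self.n_comorbid}"
            )
        if self.days_hosp_to_icu < 0:
            raise CohortError("days_hosp_to_icu must be >= 0")
        if self.mort28 not in (0, 1) or self.mv_start_within_48h not in (0, 1):
            raise CohortError("mort28 and mv_start_within_48h must be 0/1")
        if not 0 <= self.mv_days <= 28:
            raise CohortError(f"mv_days must lie in [0, 28], got {self.mv_days}")
        if self.icu_days < 0:
            raise CohortError("icu_days must be >= 0")
        if self.energy_prescribed <= 0:
            raise CohortError("energy_prescribed must be > 0")
        expected = min(math.ceil(self.icu_days), 14) if self.icu_days > 0 else 0
        if len(self.energy_received_daily) != expected:
            raise CohortError(
                "energy_received_daily must hold one value per ICU day "
                f"(capped at 14): expected {expected}, got "
                f"{len(self.energy_received_daily)}"
            )
        for name in ("bmi", "il6", "crp", "pct"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise CohortError(f"{name} must be > 0 when present, got {v}")
        if self.oral_intake_pct is not None and not 0 <= self.oral_intake_pct <= 100:
            raise CohortError("oral_intake_pct must lie in [0, 100]")
        if self.weight_loss_pct is not None and self.weight_loss_pct < 0:
            raise CohortError("weight_loss_pct must be >= 0")


def compute_vfd(record: PatientRecord, *, death_zero: bool = True) -> int:
    """Ventilator-free days within 28 days.

    Survivors get ``28 - min(mv_days, 28)``; 28-day non-survivors get 0
    under the usual convention (set ``death_zero=False`` to score
    decedents like survivors instead).
    """
    if record.mv_days < 0:
        raise CohortError("mv_days must be >= 0")
    if record.mort28 == 1 and death_zero:
        return 0
    return int(round(28 - min(record.mv_days, 28)))


def _format_value(name: str, value) -> str:
    if value is None:
        return ""
    if name == "energy_received_daily":
        return ";".join(repr(float(v)) for v in value)
    if name in _INT_FIELDS:
        return str(int(value))
    return repr(value) if isinstance(value, float) else str(value)


def write_cohort(
    records: Iterable[PatientRecord], path, *, missing_token: str = ""
) -> None:
    """Write a cohort to a UTF-8 CSV with the canonical header."""
    rows = []
    for rec in records:
        row = {}
        for f in fields(rec):
            s = _format_value(f.name, getattr(rec, f.name))
            row[f.name] = missing_token if s == "" else s
        rows.append(row)
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    missing_token: str = "",
) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    ``schema`` maps canonical field names to the file's column names when
    they differ. Rows violating a hard invariant are rejected with a
    row-indexed message; a missing required column raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    colmap = {name: (schema or {}).get(name, name) for name in COLUMNS}
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")

    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        kwargs = {}
        for name, col in colmap.items():
            raw = row[col].strip()
            if raw == missing_token or raw == "":
                if name in OPTIONAL_FIELDS:
                    kwargs[name] = None
                    continue
                raise SchemaError(f"row {idx}: required field '{name}' is empty")
            if name == "patient_id":
                kwargs[name] = raw
            elif name == "energy_received_daily":
                try:
                    kwargs[name] = [float(v) for v in raw.split(";") if v != ""]
                except ValueError:
                    raise SchemaError(
                        f"row {idx}: cannot parse '{col}' value '{raw}'"
                    ) from None
            else:
                try:
                    value = float(raw)
                except ValueError:
                    raise SchemaError(
                        f"row {idx}: non-numeric value '{raw}' in column '{col}'"
                    ) from None
                kwargs[name] = int(value) if name in _INT_FIELDS else value
        try:
            records.append(PatientRecord(**kwargs))
        except CohortError as exc:
            raise CohortError(f"row {idx}: {exc}") from None
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (energy list kept as Python lists)."""
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in fields(r)} for r in records],
        columns=COLUMNS,
    )


def with_vfd(records: Sequence[PatientRecord], *, death_zero: bool = True) -> pd.DataFrame:
    """Cohort frame with a ``vfd`` column appended."""
    df = cohort_to_frame(records)
    df["vfd"] = [compute_vfd(r, death_zero=death_zero) for r in records]
    return df
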