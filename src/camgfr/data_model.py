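"""Domain types and cohort I/O.

A :class:`PatientRecord` carries the covariates every GFR-estimation equation
needs — age, sex, height, weight, serum creatinine — plus, when available, a
reference ("measured") GFR from an isotope-clearance study and the number of
days between the creatinine draw and that study.  A :class:`Cohort` is an
ordered collection of records with a single creatinine unit.

The canonical internal creatinine unit is µmol/L (UK laboratory convention);
every downstream equation converts from it at a single point, which keeps
unit handling in one place.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MG_DL_TO_UMOL_L",
    "UMOL_L",
    "MG_DL",
    "PatientRecord",
    "Cohort",
    "RowIssue",
    "validate_record",
    "convert_creatinine",
    "du_bois_bsa",
    "read_cohort",
    "write_cohort",
    "split_cohort",
]

#: 1 mg/dL of creatinine = 88.42 µmol/L (molar mass 113.12 g/mol).
MG_DL_TO_UMOL_L = 88.42

UMOL_L = "umol/L"
MG_DL = "mg/dL"

_UNIT_ALIASES = {
    "umol/l": UMOL_L,
    "µmol/l": UMOL_L,
    "μmol/l": UMOL_L,
    "mg/dl": MG_DL,
}

#: Records admitted to analysis must have the creatinine drawn within this
#: many days of the reference GFR measurement.
MAX_DAYS_BETWEEN = 30

#: Minimum age (years) for inclusion.
MIN_AGE = 18.0

CSV_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "creatinine",
    "creatinine_unit",
    "measured_gfr",
    "days_between",
]
_REQUIRED_COLUMNS = CSV_COLUMNS[:7]


class UnitError(ValueError):
    """Unknown or mismatched concentration unit."""


class SchemaError(ValueError):
    """Input file does not provide the required columns."""


class SplitError(ValueError):
    """Cohort cannot be partitioned as requested."""


def normalize_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip().lower()]
    except KeyError:
        raise UnitError(
            f"unknown creatinine unit {unit!r}; expected {UMOL_L!r} or {MG_DL!r}"
        ) from None


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates and optional reference GFR.

    Parameters
    ----------
    patient_id : opaque identifier
    age : years
    sex : ``"M"`` or ``"F"``
    height : cm
    weight : kg
    creatinine : serum creatinine concentration in `creatinine_unit`
    creatinine_unit : ``"umol/L"`` or ``"mg/dL"``
    measured_gfr : reference GFR in mL/min, or None
    days_between : days between creatinine draw and GFR measurement, or None
    """

    patient_id: str
    age: float
    sex: str
    height: float
    weight: float
    creatinine: float
    creatinine_unit: str = UMOL_L
    measured_gfr: float | None = None
    days_between: float | None = None

    @property
    def is_male(self) -> bool:
        return self.sex.upper() == "M"

    @property
    def bsa(self) -> float:
        return du_bois_bsa(self.height, self.weight)

    def creatinine_in(self, unit: str) -> float:
        return convert_creatinine(self.creatinine, self.creatinine_unit, unit)


@dataclass
class Cohort:
    """Ordered collection of patient records sharing one creatinine unit."""

    records: list[PatientRecord]
    label: str = ""
    creatinine_unit: str = UMOL_L

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def measured_gfr(self) -> np.ndarray:
        """Vector of measured GFR values (mL/min); raises if any is absent."""
        vals = [r.measured_gfr for r in self.records]
        if any(v is None for v in vals):
            missing = sum(v is None for v in vals)
            raise ValueError(f"{missing} record(s) lack measured_gfr")
        return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class RowIssue:
    """A rejected or malformed input row, with the reason it was rejected."""

    row_number: int
    patient_id: str
    problems: tuple[str, ...]


def validate_record(record: PatientRecord) -> list[str]:
    """Check a record against the inclusion rules; never raises.

    Returns an empty list iff the record is admissible: adults only
    (age ≥ 18), positive anthropometrics and creatinine, a positive measured
    GFR when present, and a creatinine draw within 30 days of the reference
    GFR measurement when the interval is recorded.
    """
    problems: list[str] = []
    if not record.age >= MIN_AGE:
        problems.append(f"age: must be >= {MIN_AGE:g} years (got {record.age!r})")
    if not record.height > 0:
        problems.append(f"height: must be positive cm (got {record.height!r})")
    if not record.weight > 0:
        problems.append(f"weight: must be positive kg (got {record.weight!r})")
    if not record.creatinine > 0:
        problems.append(f"creatinine: must be positive (got {record.creatinine!r})")
    if record.measured_gfr is not None and not record.measured_gfr > 0:
        problems.append(
            f"measured_gfr: must be positive mL/min when present (got {record.measured_gfr!r})"
        )
    if record.days_between is not None and not record.days_between <= MAX_DAYS_BETWEEN:
        problems.append(
            f"days_between: creatinine must be within {MAX_DAYS_BETWEEN} days of the "
            f"GFR measurement (got {record.days_between!r})"
        )
    return problems


def convert_creatinine(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a creatinine concentration between µmol/L and mg/dL.

    mg/dL → µmol/L multiplies by 88.42; the inverse divides; same-unit
    conversion is the identity.
    """
    src, dst = normalize_unit(from_unit), normalize_unit(to_unit)
    if src == dst:
        return value
    if src == MG_DL:  # dst is umol/L
        return value * MG_DL_TO_UMOL_L
    return value / MG_DL_TO_UMOL_L


def du_bois_bsa(height: float, weight: float) -> float:
    """Du Bois body surface area (m²) from height (cm) and weight (kg).

    BSA = 0.007184 × height^0.725 × weight^0.425.
    """
    if not (height > 0 and weight > 0):
        raise ValueError(f"height and weight must be positive (got {height}, {weight})")
    return 0.007184 * height**0.725 * weight**0.425


def _parse_float(raw: str, column: str, problems: list[str]) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        problems.append(f"{column}: not numeric ({raw!r})")
        return None


def read_cohort(
    path: str | Path,
    unit: str = UMOL_L,
    label: str | None = None,
) -> tuple[Cohort, list[RowIssue]]:
    """Read a cohort CSV, converting creatinine to `unit`.

    The file must be comma-separated UTF-8 with a header row naming at least
    ``patient_id,age,sex,height_cm,weight_kg,creatinine,creatinine_unit``;
    ``measured_gfr`` and ``days_between`` are optional, missing values are
    empty strings, and sex is ``M``/``F`` (case-insensitive).

    Rows that fail to parse or violate the record invariants are collected
    into the returned issue list — never silently dropped — and file order of
    the accepted records is preserved.
    """
    path = Path(path)
    unit = normalize_unit(unit)
    records: list[PatientRecord] = []
    issues: list[RowIssue] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing_cols:
            raise SchemaError(f"{path}: missing required column(s) {missing_cols}")
        for i, row in enumerate(reader, start=2):  # line 1 is the header
            problems: list[str] = []
            pid = (row.get("patient_id") or "").strip()
            age = _parse_float(row.get("age", ""), "age", problems)
            height = _parse_float(row.get("height_cm", ""), "height_cm", problems)
            weight = _parse_float(row.get("weight_kg", ""), "weight_kg", problems)
            cre = _parse_float(row.get("creatinine", ""), "creatinine", problems)
            mgfr = _parse_float(row.get("measured_gfr", ""), "measured_gfr", problems)
            days = _parse_float(row.get("days_between", ""), "days_between", problems)
            sex = (row.get("sex") or "").strip().upper()
            if sex not in ("M", "F"):
                problems.append(f"sex: expected M or F (got {row.get('sex')!r})")
            for col, val in (("age", age), ("height_cm", height),
                             ("weight_kg", weight), ("creatinine", cre)):
                if val is None and not any(p.startswith(col) for p in problems):
                    problems.append(f"{col}: required value is missing")
            try:
                row_unit = normalize_unit(row.get("creatinine_unit") or "")
            except UnitError as exc:
                problems.append(str(exc))
                row_unit = unit
            if problems:
                issues.append(RowIssue(i, pid, tuple(problems)))
                continue
            record = PatientRecord(
                patient_id=pid,
                age=age,
                sex=sex,
                height=height,
                weight=weight,
                creatinine=convert_creatinine(cre, row_unit, unit),
                creatinine_unit=unit,
                measured_gfr=mgfr,
                days_between=days,
            )
            violations = validate_record(record)
            if violations:
                issues.append(RowIssue(i, pid, tuple(violations)))
            else:
                records.append(record)
    return Cohort(records, label=label or path.stem, creatinine_unit=unit), issues


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the standard CSV schema.

    Floats are written with ``repr`` so a read/write round-trip reproduces
    every value bit-for-bit.
    """
    path = Path(path)

    def fmt(v: float | None) -> str:
        return "" if v is None else repr(float(v))

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort.records:
            writer.writerow(
                [
                    r.patient_id,
                    fmt(r.age),
                    r.sex,
                    fmt(r.height),
                    fmt(r.weight),
                    fmt(r.creatinine),
                    r.creatinine_unit,
                    fmt(r.measured_gfr),
                    fmt(r.days_between),
                ]
            )


def _dev_size(n: int, ratio: float) -> int:
    # round half away from zero, so e.g. 2471 × 0.8 → 1977 exactly
    return int(math.floor(n * ratio + 0.5))


def split_cohort(
    cohort: Cohort, ratio: float = 0.8, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Randomly partition a cohort into development and validation parts.

    The development part receives ``round(ratio × n)`` records (half away
    from zero); assignment is a simple seeded random draw with no
    stratification, record order within each part follows the input cohort,
    and the same seed always yields the same partition.
    """
    if not 0 < ratio < 1:
        raise SplitError(f"ratio must be in (0, 1), got {ratio}")
    n = len(cohort)
    if n < 2:
        raise SplitError(f"need at least 2 records to split, got {n}")
    n_dev = _dev_size(n, ratio)
    rng = np.random.default_rng(seed)
    dev_idx = np.sort(rng.permutation(n)[:n_dev])
    mask = np.zeros(n, dtype=bool)
    mask[dev_idx] = True
    dev = [r for r, m in zip(cohort.records, mask) if m]
    val = [r for r, m in zip(cohort.records, mask) if not m]
    return (
        Cohort(dev, label=f"{cohort.label}/development", creatinine_unit=cohort.creatinine_unit),
        Cohort(val, label=f"{cohort.label}/validation", creatinine_unit=cohort.creatinine_unit),
    )
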