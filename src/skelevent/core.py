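"""Core domain types and delimited-text I/O for claims and patient tables.

The package works on a deliberately flat claims schema — one row per billed
service line with a service date, a code and its coding system — rather than
any native Medicare file layout. Dates are ISO-8601 calendar dates and all
day arithmetic is exact calendar-day differences.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "CodeSystem",
    "Claim",
    "Patient",
    "StudyConfig",
    "DateInterval",
    "InvalidCodeError",
    "SchemaError",
    "ValidationError",
    "normalize_code",
    "read_claims",
    "write_claims",
    "read_patients",
    "write_patients",
]


class InvalidCodeError(ValueError):
    """Raised when a raw code string cannot be normalized."""


class SchemaError(ValueError):
    """Raised when an input table is missing columns or uses an unknown dialect."""


class ValidationError(ValueError):
    """Raised when row contents violate a domain invariant."""


class CodeSystem(enum.Enum):
    """Coding system of a claim line.

    ICD9_DX — ICD-9-CM diagnosis codes (clinical events: fractures, cord
    compression, external-cause E-codes). ICD9_PX — ICD-9-CM procedure codes.
    HCPCS — HCPCS/CPT procedure codes from physician and outpatient claims.
    """

    ICD9_DX = "ICD9_DX"
    ICD9_PX = "ICD9_PX"
    HCPCS = "HCPCS"


def normalize_code(raw: str, system: CodeSystem | None = None) -> str:
    """Normalize a raw code string: strip whitespace and dots, upper-case.

    Idempotent. ``system`` is accepted for interface symmetry; normalization
    is identical across the three systems.

    Raises
    ------
    InvalidCodeError
        If ``raw`` is empty or whitespace-only.
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    out = raw.strip().replace(".", "").upper()
    if not out:
        raise InvalidCodeError(f"empty code after normalization: {raw!r}")
    return out


@dataclass(frozen=True, order=True)
class DateInterval:
    """Closed calendar-date interval [start, end]."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"interval end {self.end} before start {self.start}"
            )

    def covers(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class Claim:
    """One billed service line."""

    claim_id: str
    patient_id: str
    service_date: dt.date
    code: str  # normalized: dots stripped, upper-cased
    system: CodeSystem


@dataclass(frozen=True)
class Patient:
    """One study subject: an incident metastatic prostate cancer case.

    ``ab_enrollment`` holds the Medicare Parts A/B fee-for-service coverage
    intervals; ``hmo_intervals`` holds managed-care (HMO) enrollment spells,
    during which fee-for-service claims capture is interrupted. Both lists
    are sorted and non-overlapping.
    """

    patient_id: str
    diagnosis_date: dt.date
    age_at_diagnosis: int
    death_date: dt.date | None = None
    ab_enrollment: tuple[DateInterval, ...] = ()
    hmo_intervals: tuple[DateInterval, ...] = ()
    prior_cancer_flag: bool = False
    diagnosis_month_known: bool = True
    post_mortem_diagnosis: bool = False


@dataclass(frozen=True)
class StudyConfig:
    """Study-design parameters.

    Defaults reproduce the observational design the package implements: an
    administrative study end of 2010-12-31, one year of continuous Parts A/B
    enrollment before diagnosis, a five-year prior-cancer washout, a 14-day
    trauma lookback for the fracture exclusion rule, and a minimum age of 66
    (one full year of Medicare eligibility before diagnosis).
    """

    study_end: dt.date = dt.date(2010, 12, 31)
    enrollment_lookback_days: int = 365
    prior_cancer_lookback_years: int = 5
    trauma_lookback_days: int = 14
    age_minimum: int = 66

    def __post_init__(self) -> None:
        if (
            self.enrollment_lookback_days <= 0
            or self.prior_cancer_lookback_years <= 0
            or self.trauma_lookback_days < 0
            or self.age_minimum <= 0
        ):
            raise ValidationError("lookbacks and age minimum must be positive")


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------

CLAIM_COLUMNS = ["claim_id", "patient_id", "service_date", "code", "system"]
PATIENT_COLUMNS = [
    "patient_id",
    "diagnosis_date",
    "age_at_diagnosis",
    "death_date",
    "enrollment_start",
    "enrollment_end",
    "hmo_start",
    "hmo_end",
    "prior_cancer_flag",
    "diagnosis_month_known",
    "post_mortem_diagnosis",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


def _parse_date(value, *, row: int, column: str) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return dt.date.fromisoformat(s)
    except ValueError as exc:
        raise SchemaError(f"row {row}: bad date in {column!r}: {value!r}") from exc


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_claims(path) -> list[Claim]:
    """Read a claims CSV into a list of :class:`Claim`, row order preserved.

    Columns: claim_id, patient_id, service_date, code, system. Codes are
    normalized on read. An unknown ``system`` value (e.g. an ICD-10 table)
    raises :class:`SchemaError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CLAIM_COLUMNS, path)
    claims: list[Claim] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            system = CodeSystem(row.system.strip())
        except ValueError:
            raise SchemaError(
                f"{path}: row {i}: unsupported coding system {row.system!r} "
                f"(expected one of {[s.value for s in CodeSystem]})"
            ) from None
        date = _parse_date(row.service_date, row=i, column="service_date")
        if date is None:
            raise SchemaError(f"{path}: row {i}: missing service_date")
        claims.append(
            Claim(
                claim_id=row.claim_id,
                patient_id=row.patient_id,
                service_date=date,
                code=normalize_code(row.code, system),
                system=system,
            )
        )
    return claims


def write_claims(claims: list[Claim], path) -> None:
    df = pd.DataFrame(
        [
            {
                "claim_id": c.claim_id,
                "patient_id": c.patient_id,
                "service_date": c.service_date.isoformat(),
                "code": c.code,
                "system": c.system.value,
            }
            for c in claims
        ],
        columns=CLAIM_COLUMNS,
    )
    df.to_csv(path, index=False)


def _merge_intervals(intervals: list[DateInterval]) -> tuple[DateInterval, ...]:
    """Sort and coalesce overlapping or adjacent (gap-free) intervals."""
    if not intervals:
        return ()
    out: list[DateInterval] = []
    for iv in sorted(intervals):
        if out and iv.start <= out[-1].end + dt.timedelta(days=1):
            if iv.end > out[-1].end:
                out[-1] = DateInterval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return tuple(out)


def read_patients(path) -> list[Patient]:
    """Read a patients CSV; multiple rows per patient carry extra intervals.

    Scalar fields (diagnosis date, age, flags) are taken from the first row
    of each patient and must agree across rows. Enrollment/HMO interval
    columns may be blank on any row; non-blank start/end pairs are collected,
    sorted and coalesced.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, PATIENT_COLUMNS, path)

    patients: dict[str, Patient] = {}
    ab: dict[str, list[DateInterval]] = {}
    hmo: dict[str, list[DateInterval]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        pid = row.patient_id
        if pid not in patients:
            dx = _parse_date(row.diagnosis_date, row=i, column="diagnosis_date")
            if dx is None:
                raise SchemaError(f"{path}: row {i}: missing diagnosis_date")
            try:
                age = int(row.age_at_diagnosis)
            except ValueError:
                raise SchemaError(
                    f"{path}: row {i}: bad age_at_diagnosis {row.age_at_diagnosis!r}"
                ) from None
            patients[pid] = Patient(
                patient_id=pid,
                diagnosis_date=dx,
                age_at_diagnosis=age,
                death_date=_parse_date(row.death_date, row=i, column="death_date"),
                prior_cancer_flag=_BOOL[row.prior_cancer_flag.strip().lower()],
                diagnosis_month_known=_BOOL.get(
                    row.diagnosis_month_known.strip().lower(), True
                ),
                post_mortem_diagnosis=_BOOL[row.post_mortem_diagnosis.strip().lower()],
            )
            ab[pid] = []
            hmo[pid] = []
        for start_col, end_col, store in (
            ("enrollment_start", "enrollment_end", ab),
            ("hmo_start", "hmo_end", hmo),
        ):
            start = _parse_date(getattr(row, start_col), row=i, column=start_col)
            end = _parse_date(getattr(row, end_col), row=i, column=end_col)
            if (start is None) != (end is None):
                raise ValidationError(
                    f"{path}: row {i}: {start_col}/{end_col} must be given together"
                )
            if start is not None:
                store[pid].append(DateInterval(start, end))

    return [
        replace(
            p,
            ab_enrollment=_merge_intervals(ab[pid]),
            hmo_intervals=_merge_intervals(hmo[pid]),
        )
        for pid, p in patients.items()
    ]


def write_patients(patients: list[Patient], path) -> None:
    """Write patients to CSV, one row per (patient, interval-slot)."""
    rows = []
    for p in patients:
        n = max(len(p.ab_enrollment), len(p.hmo_intervals), 1)
        for k in range(n):
            ab = p.ab_enrollment[k] if k < len(p.ab_enrollment) else None
            hm = p.hmo_intervals[k] if k < len(p.hmo_intervals) else None
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "diagnosis_date": p.diagnosis_date.isoformat(),
                    "age_at_diagnosis": p.age_at_diagnosis,
                    "death_date": p.death_date.isoformat() if p.death_date else "",
                    "enrollment_start": ab.start.isoformat() if ab else "",
                    "enrollment_end": ab.end.isoformat() if ab else "",
                    "hmo_start": hm.start.isoformat() if hm else "",
                    "hmo_end": hm.end.isoformat() if hm else "",
                    "prior_cancer_flag": str(p.prior_cancer_flag).lower(),
                    "diagnosis_month_known": str(p.diagnosis_month_known).lower(),
                    "post_mortem_diagnosis": str(p.post_mortem_diagnosis).lower(),
                }
            )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)
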