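"""Summary measures: prevalence, cumulative incidence, comparisons.

Prevalence is the proportion of cohort patients with at least one kept
event of a subtype during follow-up; cumulative incidence is the total
count of window-clustered episodes. All printed rates round half-up at the
reported precision (one decimal for percentages and per-patient means,
integer for percent changes); per-patient means use patients with ≥1
episode of that subtype as the denominator; medians over an even number of
patients take the mean of the two middle values.

The count-level helpers (:func:`percent`, :func:`per_patient_mean`,
:func:`percent_change`) are exposed so that published tables of counts can
be re-derived without the underlying line-level data.
"""

from __future__ import annotations

import datetime as dt
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .codebook import SREType
from .cohort import CohortResult
from .core import Patient
from .episodes import Episode, WindowPolicy
from .events import EventStatus, SREEvent

__all__ = [
    "round_half_up",
    "percent",
    "per_patient_mean",
    "percent_change",
    "PrevalenceRow",
    "PrevalenceTable",
    "IncidenceRow",
    "IncidenceTable",
    "ComparisonResult",
    "TimeToEventSummary",
    "prevalence_table",
    "incidence_table",
    "episode_count_change",
    "time_to_event_summary",
    "type_combination_tally",
]

ANY = "ANY"  # composite row label
_SUBTYPES = [t.value for t in SREType]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at ``decimals`` places (e.g. 0.05 → 0.1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """``numerator/denominator × 100`` rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def per_patient_mean(total: int, n_patients: int, decimals: int = 1) -> float:
    """Mean episodes per patient with ≥1 episode, reported to 1 decimal."""
    if n_patients == 0:
        return 0.0
    return round_half_up(total / n_patients, decimals)


def percent_change(value_a: float, value_b: float) -> float | None:
    """``(b − a)/a × 100`` rounded half-up to integer; None when a == 0."""
    if value_a == 0:
        return None
    return round_half_up(100.0 * (value_b - value_a) / value_a, 0)


# ---------------------------------------------------------------------------
# Prevalence (patients with ≥1 event)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceRow:
    label: str  # subtype name or "ANY"
    n_patients: int
    pct_of_cohort: float
    pct_of_sre_patients: float


@dataclass(frozen=True)
class PrevalenceTable:
    definition_name: str
    cohort_n: int
    rows: dict[str, PrevalenceRow]

    def __getitem__(self, label: str) -> PrevalenceRow:
        return self.rows[label]


def prevalence_table(
    events: list[SREEvent], cohort: CohortResult, definition_name: str
) -> PrevalenceTable:
    """Patients with ≥1 kept event, per subtype and overall."""
    cohort_n = len(cohort.included)
    if cohort_n == 0:
        raise ValueError("empty cohort")
    patients_by_type: dict[str, set[str]] = {t: set() for t in _SUBTYPES}
    any_patients: set[str] = set()
    for e in events:
        if e.status is not EventStatus.KEPT:
            continue
        patients_by_type[e.sre_type.value].add(e.patient_id)
        any_patients.add(e.patient_id)
    n_any = len(any_patients)
    rows: dict[str, PrevalenceRow] = {}
    for label in _SUBTYPES + [ANY]:
        n = n_any if label == ANY else len(patients_by_type[label])
        rows[label] = PrevalenceRow(
            label=label,
            n_patients=n,
            pct_of_cohort=percent(n, cohort_n) if cohort_n else 0.0,
            pct_of_sre_patients=percent(n, n_any) if n_any else 0.0,
        )
    return PrevalenceTable(definition_name=definition_name, cohort_n=cohort_n, rows=rows)


# ---------------------------------------------------------------------------
# Cumulative incidence (episode counts)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncidenceRow:
    label: str
    episode_total: int
    n_patients: int  # patients with ≥1 episode of this subtype
    episodes_per_patient_mean: float
    episodes_per_patient_median: float
    dist_1: int
    dist_2: int
    dist_3plus: int


@dataclass(frozen=True)
class IncidenceTable:
    window: WindowPolicy
    rows: dict[str, IncidenceRow]

    def __getitem__(self, label: str) -> IncidenceRow:
        return self.rows[label]


def _incidence_row(label: str, counts: dict[str, int]) -> IncidenceRow:
    total = sum(counts.values())
    n = len(counts)
    values = sorted(counts.values())
    return IncidenceRow(
        label=label,
        episode_total=total,
        n_patients=n,
        episodes_per_patient_mean=per_patient_mean(total, n),
        episodes_per_patient_median=float(statistics.median(values)) if values else 0.0,
        dist_1=sum(1 for v in values if v == 1),
        dist_2=sum(1 for v in values if v == 2),
        dist_3plus=sum(1 for v in values if v >= 3),
    )


def incidence_table(episodes: list[Episode], cohort: CohortResult) -> IncidenceTable:
    """Episode totals and per-patient distributions, per subtype and overall."""
    window = episodes[0].policy if episodes else WindowPolicy()
    per_type: dict[str, dict[str, int]] = {t: {} for t in _SUBTYPES}
    overall: dict[str, int] = {}
    for ep in episodes:
        counts = per_type[ep.sre_type.value]
        counts[ep.patient_id] = counts.get(ep.patient_id, 0) + 1
        overall[ep.patient_id] = overall.get(ep.patient_id, 0) + 1
    rows = {t: _incidence_row(t, per_type[t]) for t in _SUBTYPES}
    rows[ANY] = _incidence_row(ANY, overall)
    return IncidenceTable(window=window, rows=rows)


@dataclass(frozen=True)
class ComparisonResult:
    quantity: str
    value_a: float
    value_b: float
    pct_change: float | None  # (b − a)/a × 100, integer-rounded; None if a == 0


def episode_count_change(a: IncidenceTable, b: IncidenceTable) -> dict[str, ComparisonResult]:
    """Percent change in episode totals from table ``a`` to table ``b``.

    The change is signed: negative when ``b`` counts fewer episodes. A zero
    baseline yields ``pct_change=None`` rather than an exception.
    """
    out: dict[str, ComparisonResult] = {}
    for label in _SUBTYPES + [ANY]:
        va, vb = a[label].episode_total, b[label].episode_total
        out[label] = ComparisonResult(
            quantity=f"episode_total[{label}]",
            value_a=va,
            value_b=vb,
            pct_change=percent_change(va, vb),
        )
    return out


# ---------------------------------------------------------------------------
# Time-to-event and subtype combinations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeToEventSummary:
    """Median/mean day gaps: diagnosis→first SRE, first→second SRE, diagnosis→death.

    Each pair is computed over the patients for whom both endpoints exist;
    an empty stratum is reported as None. First/second SREs are episode
    anchor dates ordered in time, pooling all subtypes.
    """

    dx_to_first_median: float | None
    dx_to_first_mean: float | None
    first_to_second_median: float | None
    first_to_second_mean: float | None
    dx_to_death_median: float | None
    dx_to_death_mean: float | None
    n_first: int
    n_second: int
    n_death: int


def _med_mean(gaps: list[int]) -> tuple[float | None, float | None]:
    if not gaps:
        return None, None
    return float(statistics.median(gaps)), round_half_up(statistics.mean(gaps), 1)


def time_to_event_summary(
    episodes: list[Episode], patients: list[Patient], cohort: CohortResult
) -> TimeToEventSummary:
    dx = {p.patient_id: p.diagnosis_date for p in patients}
    anchors: dict[str, list[dt.date]] = {}
    for ep in episodes:
        anchors.setdefault(ep.patient_id, []).append(ep.anchor_date)
    first_gaps, second_gaps = [], []
    for pid, dates in anchors.items():
        dates = sorted(dates)
        first_gaps.append((dates[0] - dx[pid]).days)
        if len(dates) > 1:
            second_gaps.append((dates[1] - dates[0]).days)
    death_gaps = [
        (p.death_date - p.diagnosis_date).days
        for p in patients
        if p.patient_id in cohort.included and p.death_date is not None
    ]
    f_med, f_mean = _med_mean(first_gaps)
    s_med, s_mean = _med_mean(second_gaps)
    d_med, d_mean = _med_mean(death_gaps)
    return TimeToEventSummary(
        dx_to_first_median=f_med,
        dx_to_first_mean=f_mean,
        first_to_second_median=s_med,
        first_to_second_mean=s_mean,
        dx_to_death_median=d_med,
        dx_to_death_mean=d_mean,
        n_first=len(first_gaps),
        n_second=len(second_gaps),
        n_death=len(death_gaps),
    )


def type_combination_tally(
    events: list[SREEvent],
) -> tuple[dict[frozenset[SREType], int], float]:
    """Partition SRE patients by the exact set of subtypes they experienced.

    Returns the per-combination patient counts and the share (percent, one
    decimal) of SRE patients with two or more subtypes.
    """
    by_patient: dict[str, set[SREType]] = {}
    for e in events:
        if e.status is EventStatus.KEPT:
            by_patient.setdefault(e.patient_id, set()).add(e.sre_type)
    tally: dict[frozenset[SREType], int] = {}
    multi = 0
    for types in by_patient.values():
        key = frozenset(types)
        tally[key] = tally.get(key, 0) + 1
        if len(key) >= 2:
            multi += 1
    share = percent(multi, len(by_patient)) if by_patient else 0.0
    return tally, share
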