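"""Cohort selection and follow-up/censoring computation.

Inclusion requires: age at diagnosis at or above the study minimum (66 by
default, guaranteeing a full year of Medicare claims before diagnosis), a
known diagnosis month, a diagnosis made before death (not at autopsy), no
cancer history in the washout window, continuous Parts A/B fee-for-service
enrollment across the lookback year, and no SRE-coded claim before the
diagnosis date. Exclusion reasons are logged first-failure-only, in that
fixed order, so the attrition log is deterministic.

The prior-SRE screen uses the union of all tiers and subtypes of the event
code lists, so the selected cohort does not depend on which composite
definition is evaluated downstream.

Follow-up runs from the diagnosis date to the earliest of: first HMO
enrollment on/after diagnosis, the day Parts A/B coverage lapses, death, or
the administrative study end.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass

from .codebook import Codebook, Role, match_code
from .core import Claim, DateInterval, Patient, StudyConfig

__all__ = ["ExclusionReason", "CohortResult", "select_cohort", "follow_up_end"]


class ExclusionReason(enum.Enum):
    UNDER_AGE = "UNDER_AGE"
    UNKNOWN_DX_DATE = "UNKNOWN_DX_DATE"
    POST_MORTEM_DX = "POST_MORTEM_DX"
    PRIOR_CANCER = "PRIOR_CANCER"
    NOT_CONTINUOUSLY_ENROLLED = "NOT_CONTINUOUSLY_ENROLLED"
    PRIOR_SRE = "PRIOR_SRE"


@dataclass(frozen=True)
class CohortResult:
    included: frozenset[str]
    exclusion_log: tuple[tuple[str, ExclusionReason], ...]
    follow_up: dict[str, tuple[dt.date, dt.date]]  # patient_id -> (start, end)

    def is_included(self, patient_id: str) -> bool:
        return patient_id in self.included


def _continuously_enrolled(
    intervals: tuple[DateInterval, ...], start: dt.date, end: dt.date
) -> bool:
    """True iff [start, end] is covered by the union of intervals with no gap."""
    day = start
    for iv in intervals:  # sorted, non-overlapping
        if iv.start > day:
            break
        if iv.end >= day:
            day = iv.end + dt.timedelta(days=1)
            if day > end:
                return True
    return day > end


def follow_up_end(patient: Patient, config: StudyConfig) -> dt.date:
    """Censoring date: min of HMO start, A/B lapse, death, study end."""
    candidates = [config.study_end]
    if patient.death_date is not None:
        candidates.append(patient.death_date)
    for iv in patient.hmo_intervals:
        if iv.end >= patient.diagnosis_date:
            candidates.append(max(iv.start, patient.diagnosis_date))
            break
    for iv in patient.ab_enrollment:
        if iv.covers(patient.diagnosis_date):
            candidates.append(iv.end + dt.timedelta(days=1))
            break
    else:
        # not covered on the diagnosis day itself: coverage lapsed already
        candidates.append(patient.diagnosis_date)
    return min(candidates)


def select_cohort(
    patients: list[Patient],
    claims: list[Claim],
    codebook: Codebook,
    config: StudyConfig | None = None,
) -> CohortResult:
    """Apply inclusion/exclusion rules and compute each patient's follow-up.

    Raises a referential-integrity error when a claim names a patient absent
    from the patient table.
    """
    config = config or StudyConfig()
    by_patient: dict[str, list[Claim]] = {p.patient_id: [] for p in patients}
    for c in claims:
        if c.patient_id not in by_patient:
            raise KeyError(
                f"claim {c.claim_id!r} references unknown patient {c.patient_id!r}"
            )
        by_patient[c.patient_id].append(c)

    included: set[str] = set()
    log: list[tuple[str, ExclusionReason]] = []
    follow_up: dict[str, tuple[dt.date, dt.date]] = {}

    for p in patients:
        reason = _first_failure(p, by_patient[p.patient_id], codebook, config)
        if reason is not None:
            log.append((p.patient_id, reason))
            continue
        included.add(p.patient_id)
        follow_up[p.patient_id] = (p.diagnosis_date, follow_up_end(p, config))

    return CohortResult(
        included=frozenset(included),
        exclusion_log=tuple(log),
        follow_up=follow_up,
    )


def _first_failure(
    p: Patient,
    claims: list[Claim],
    codebook: Codebook,
    config: StudyConfig,
) -> ExclusionReason | None:
    if p.age_at_diagnosis < config.age_minimum:
        return ExclusionReason.UNDER_AGE
    if not p.diagnosis_month_known:
        return ExclusionReason.UNKNOWN_DX_DATE
    if p.post_mortem_diagnosis or (
        p.death_date is not None and p.death_date < p.diagnosis_date
    ):
        return ExclusionReason.POST_MORTEM_DX
    if p.prior_cancer_flag:
        return ExclusionReason.PRIOR_CANCER
    lookback_start = p.diagnosis_date - dt.timedelta(days=config.enrollment_lookback_days)
    if not _continuously_enrolled(p.ab_enrollment, lookback_start, p.diagnosis_date):
        return ExclusionReason.NOT_CONTINUOUSLY_ENROLLED
    # prior-SRE screen: any pre-diagnosis claim matching any event code, any tier
    for c in claims:
        if c.service_date < p.diagnosis_date and any(
            role is Role.EVENT for _, _, role in match_code(codebook, c.code, c.system)
        ):
            return ExclusionReason.PRIOR_SRE
    return None
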