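"""Turn claims into per-day SRE events under a composite definition.

Events are day-granular: all same-day claims of one subtype collapse into a
single event-day, since claims carry no intra-day ordering. Every candidate
is retained in the output with an explicit status (audit trail); the KEPT
subset is the analytic set.

The fracture trauma-exclusion rule: an "other fracture" event (a pathologic
fracture identified only through the sensitivity-extension codes) is
excluded when a non-exempt accident/fall E-code claim appears within the
trauma lookback window (14 days, inclusive on both ends, up to and including
the fracture day) — such fractures are attributed to the trauma rather than
to cancer-weakened bone. Same-level-fall E-codes (slips and trips during
routine activity) are exempt and never trigger the exclusion, but do not
shield against a distinct non-exempt trauma code in the window. Fractures
carrying a specific pathologic-fracture code are never trauma-excluded.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, replace

from .codebook import Codebook, Role, SREDefinition, SREType, Tier, match_code
from .cohort import CohortResult
from .core import Claim, StudyConfig

__all__ = [
    "EventStatus",
    "SREEvent",
    "identify_events",
    "apply_trauma_exclusion",
    "apply_same_day_hierarchy",
    "kept",
    "write_events",
    "read_events",
]


class EventStatus(enum.Enum):
    KEPT = "KEPT"
    EXCLUDED_TRAUMA = "EXCLUDED_TRAUMA"
    EXCLUDED_HIERARCHY = "EXCLUDED_HIERARCHY"
    EXCLUDED_CONCURRENCY = "EXCLUDED_CONCURRENCY"
    EXCLUDED_OUTSIDE_FOLLOWUP = "EXCLUDED_OUTSIDE_FOLLOWUP"


@dataclass(frozen=True)
class SREEvent:
    patient_id: str
    date: dt.date
    sre_type: SREType
    matched_tier: Tier
    source_claim_ids: tuple[str, ...]
    status: EventStatus


def kept(events: list[SREEvent]) -> list[SREEvent]:
    """The analytic subset: events with status KEPT."""
    return [e for e in events if e.status is EventStatus.KEPT]


def _claim_roles(codebook: Codebook, claim: Claim) -> set[Role]:
    return {role for _, _, role in match_code(codebook, claim.code, claim.system)}


def _is_nonexempt_trauma(codebook: Codebook, claim: Claim) -> bool:
    roles = _claim_roles(codebook, claim)
    return Role.TRAUMA in roles and Role.SAME_LEVEL_FALL not in roles


def identify_events(
    claims: list[Claim],
    codebook: Codebook,
    definition: SREDefinition,
    cohort: CohortResult,
    config: StudyConfig | None = None,
) -> list[SREEvent]:
    """Identify per-day SRE subtype events for cohort patients.

    Claims of included patients are matched against the codebook; event
    matches whose tier the definition selects become candidate event-days.
    Candidates outside the patient's follow-up interval are flagged, the
    trauma-exclusion rule is applied to sensitivity-tier fractures, and any
    enabled option flags (same-day hierarchy, radiotherapy concurrency
    filter, bone-surgery trauma lookback) run last. Output order is sorted
    (patient, date, subtype) and independent of claim-row order.
    """
    config = config or StudyConfig()

    # candidate event-days: (pid, date, subtype) -> (best tier, claim ids)
    candidates: dict[tuple[str, dt.date, SREType], dict] = {}
    for c in claims:
        if c.patient_id not in cohort.included:
            continue
        for sre_type, tier, role in match_code(codebook, c.code, c.system):
            if role is not Role.EVENT or not definition.selects(sre_type, tier):
                continue
            key = (c.patient_id, c.service_date, sre_type)
            slot = candidates.setdefault(key, {"tier": tier, "claims": set()})
            slot["claims"].add(c.claim_id)
            # a specific-tier claim upgrades the whole event-day
            if tier is Tier.SPECIFICITY:
                slot["tier"] = Tier.SPECIFICITY

    events = [
        SREEvent(
            patient_id=pid,
            date=date,
            sre_type=sre_type,
            matched_tier=slot["tier"],
            source_claim_ids=tuple(sorted(slot["claims"])),
            status=EventStatus.KEPT,
        )
        for (pid, date, sre_type), slot in candidates.items()
    ]
    events.sort(key=lambda e: (e.patient_id, e.date, e.sre_type.value))

    # follow-up containment
    events = [
        e
        if cohort.follow_up[e.patient_id][0] <= e.date <= cohort.follow_up[e.patient_id][1]
        else replace(e, status=EventStatus.EXCLUDED_OUTSIDE_FOLLOWUP)
        for e in events
    ]

    events = apply_trauma_exclusion(
        events, claims, codebook, config.trauma_lookback_days
    )
    if definition.bs_trauma_lookback:
        events = _apply_bs_trauma_lookback(
            events, claims, codebook, config.trauma_lookback_days
        )
    events = apply_same_day_hierarchy(events, definition.same_day_hierarchy)
    if definition.rad_concurrency_filter:
        events = _apply_rad_concurrency(events, claims, codebook)
    return events


def _trauma_days(claims: list[Claim], codebook: Codebook) -> dict[str, set[dt.date]]:
    days: dict[str, set[dt.date]] = {}
    for c in claims:
        if _is_nonexempt_trauma(codebook, c):
            days.setdefault(c.patient_id, set()).add(c.service_date)
    return days


def _has_trauma_in_window(
    trauma_days: set[dt.date], day: dt.date, lookback_days: int
) -> bool:
    lo = day - dt.timedelta(days=lookback_days)
    return any(lo <= t <= day for t in trauma_days)


def apply_trauma_exclusion(
    events: list[SREEvent],
    claims: list[Claim],
    codebook: Codebook,
    lookback_days: int,
) -> list[SREEvent]:
    """Exclude sensitivity-tier PF events preceded by non-exempt trauma.

    The window is ``[d - lookback_days, d]`` inclusive: a trauma claim on
    the fracture day itself, or up to ``lookback_days`` before, excludes.
    Specific-tier PF events and other subtypes pass through untouched.
    """
    trauma = _trauma_days(claims, codebook)
    out = []
    for e in events:
        if (
            e.status is EventStatus.KEPT
            and e.sre_type is SREType.PF
            and e.matched_tier is Tier.SENSITIVITY_EXT
            and _has_trauma_in_window(
                trauma.get(e.patient_id, set()), e.date, lookback_days
            )
        ):
            e = replace(e, status=EventStatus.EXCLUDED_TRAUMA)
        out.append(e)
    return out


def _apply_bs_trauma_lookback(
    events: list[SREEvent],
    claims: list[Claim],
    codebook: Codebook,
    lookback_days: int,
) -> list[SREEvent]:
    # literature variant: bone surgery not counted when preceded by trauma
    trauma = _trauma_days(claims, codebook)
    out = []
    for e in events:
        if (
            e.status is EventStatus.KEPT
            and e.sre_type is SREType.BS
            and _has_trauma_in_window(
                trauma.get(e.patient_id, set()), e.date, lookback_days
            )
        ):
            e = replace(e, status=EventStatus.EXCLUDED_TRAUMA)
        out.append(e)
    return out


def apply_same_day_hierarchy(
    events: list[SREEvent], enabled: bool
) -> list[SREEvent]:
    """Optionally let clinical events outrank same-day treatment events.

    When enabled, a RAD or BS event-day is excluded if the same patient has
    a KEPT PF or SCC event that day (treatment on the day of a clinical
    event is read as treatment *of* that event). No-op when disabled.
    """
    if not enabled:
        return events
    clinical = {
        (e.patient_id, e.date)
        for e in events
        if e.status is EventStatus.KEPT
        and e.sre_type in (SREType.PF, SREType.SCC)
    }
    out = []
    for e in events:
        if (
            e.status is EventStatus.KEPT
            and e.sre_type in (SREType.RAD, SREType.BS)
            and (e.patient_id, e.date) in clinical
        ):
            e = replace(e, status=EventStatus.EXCLUDED_HIERARCHY)
        out.append(e)
    return out


def _apply_rad_concurrency(
    events: list[SREEvent], claims: list[Claim], codebook: Codebook
) -> list[SREEvent]:
    # literature variant: RAD counted only with a same-day bone-related
    # diagnosis (bone metastasis / bone pain context code, or a PF/SCC claim)
    context: set[tuple[str, dt.date]] = set()
    for c in claims:
        for sre_type, _, role in match_code(codebook, c.code, c.system):
            if role is Role.RAD_CONTEXT or (
                role is Role.EVENT and sre_type in (SREType.PF, SREType.SCC)
            ):
                context.add((c.patient_id, c.service_date))
    out = []
    for e in events:
        if (
            e.status is EventStatus.KEPT
            and e.sre_type is SREType.RAD
            and (e.patient_id, e.date) not in context
        ):
            e = replace(e, status=EventStatus.EXCLUDED_CONCURRENCY)
        out.append(e)
    return out


def write_events(events: list[SREEvent], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "date": e.date.isoformat(),
                "sre_type": e.sre_type.value,
                "matched_tier": e.matched_tier.value,
                "status": e.status.value,
                "source_claim_ids": ";".join(e.source_claim_ids),
            }
            for e in events
        ],
        columns=[
            "patient_id",
            "date",
            "sre_type",
            "matched_tier",
            "status",
            "source_claim_ids",
        ],
    ).to_csv(path, index=False)


def read_events(path) -> list[SREEvent]:
    import pandas as pd

    from .codebook import Tier

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        SREEvent(
            patient_id=r.patient_id,
            date=dt.date.fromisoformat(r.date),
            sre_type=SREType(r.sre_type),
            matched_tier=Tier(r.matched_tier),
            source_claim_ids=tuple(x for x in r.source_claim_ids.split(";") if x),
            status=EventStatus(r.status),
        )
        for r in df.itertuples(index=False)
    ]
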