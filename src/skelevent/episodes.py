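"""Cluster per-day SRE events into episodes under a window policy.

Claims generated during one clinical episode of care arrive spread over
days to weeks (radiotherapy fractions, surgical follow-up), so counting raw
event-days overstates incidence. A window policy groups event-days of one
subtype for one patient into episodes: under ``EPISODE_START`` anchoring a
new event-day joins the open episode iff it falls within ``length_days`` of
the episode's *first* day (the counted event); under ``ROLLING`` it joins
iff within ``length_days`` of the episode's *most recent* day. Boundaries
are inclusive: a day exactly ``length_days`` after the anchor still joins.

Clustering is strictly within subtype; a spinal-cord-compression day never
merges into a fracture episode.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from itertools import groupby

from .codebook import SREType
from .events import EventStatus, SREEvent

__all__ = [
    "Anchoring",
    "WindowPolicy",
    "Episode",
    "cluster_episodes",
    "brute_force_cluster",
]


class Anchoring(enum.Enum):
    EPISODE_START = "EPISODE_START"
    ROLLING = "ROLLING"


@dataclass(frozen=True)
class WindowPolicy:
    """Maximum episode window in days, and how the window is anchored."""

    length_days: int = 21
    anchoring: Anchoring = Anchoring.EPISODE_START

    def __post_init__(self) -> None:
        if self.length_days < 0:
            raise ValueError("length_days must be >= 0")


@dataclass(frozen=True)
class Episode:
    patient_id: str
    sre_type: SREType
    anchor_date: dt.date
    last_event_date: dt.date
    n_event_days: int
    policy: WindowPolicy


def cluster_episodes(
    events: list[SREEvent], policy: WindowPolicy | None = None
) -> list[Episode]:
    """Cluster KEPT event-days into episodes per (patient, subtype).

    Input must be the analytic (KEPT) event set; a non-KEPT event is a
    contract violation. Episodes are returned chronologically ordered
    within each (patient, subtype) group.
    """
    policy = policy or WindowPolicy()
    bad = [e for e in events if e.status is not EventStatus.KEPT]
    if bad:
        raise ValueError(
            f"cluster_episodes expects KEPT events only; got {bad[0].status.value}"
        )

    def group_key(e: SREEvent) -> tuple[str, str]:
        return (e.patient_id, e.sre_type.value)

    episodes: list[Episode] = []
    ordered = sorted(events, key=lambda e: (group_key(e), e.date))
    for (pid, type_value), grp in groupby(ordered, group_key):
        days = sorted({e.date for e in grp})
        episodes.extend(_cluster_one(pid, SREType(type_value), days, policy))
    return episodes


def _cluster_one(
    pid: str, sre_type: SREType, days: list[dt.date], policy: WindowPolicy
) -> list[Episode]:
    episodes: list[Episode] = []
    anchor: dt.date | None = None
    last: dt.date | None = None
    n = 0

    def flush() -> None:
        if anchor is not None:
            episodes.append(
                Episode(
                    patient_id=pid,
                    sre_type=sre_type,
                    anchor_date=anchor,
                    last_event_date=last,
                    n_event_days=n,
                    policy=policy,
                )
            )

    for d in days:
        if anchor is not None:
            ref = anchor if policy.anchoring is Anchoring.EPISODE_START else last
            if (d - ref).days <= policy.length_days:
                last = d
                n += 1
                continue
            flush()
        anchor = last = d
        n = 1
    flush()
    return episodes


def brute_force_cluster(event_days: list[dt.date], policy: WindowPolicy) -> int:
    """Reference episode count for one patient and subtype (test oracle).

    Independent linear scan over a sorted day list; raises on unsorted
    input. Used only to cross-check :func:`cluster_episodes`.
    """
    if list(event_days) != sorted(event_days):
        raise ValueError("event_days must be sorted ascending")
    count = 0
    anchor: dt.date | None = None
    prev: dt.date | None = None
    for d in event_days:
        if anchor is None:
            count += 1
            anchor = prev = d
            continue
        ref = anchor if policy.anchoring is Anchoring.EPISODE_START else prev
        if (d - ref).days <= policy.length_days:
            prev = d
        else:
            count += 1
            anchor = prev = d
    return count


def write_episodes(episodes: list[Episode], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "patient_id": ep.patient_id,
                "sre_type": ep.sre_type.value,
                "anchor_date": ep.anchor_date.isoformat(),
                "last_event_date": ep.last_event_date.isoformat(),
                "n_event_days": ep.n_event_days,
                "window_days": ep.policy.length_days,
                "anchoring": ep.policy.anchoring.value,
            }
            for ep in episodes
        ],
        columns=[
            "patient_id",
            "sre_type",
            "anchor_date",
            "last_event_date",
            "n_event_days",
            "window_days",
            "anchoring",
        ],
    ).to_csv(path, index=False)


def read_episodes(path) -> list[Episode]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Episode(
            patient_id=r.patient_id,
            sre_type=SREType(r.sre_type),
            anchor_date=dt.date.fromisoformat(r.anchor_date),
            last_event_date=dt.date.fromisoformat(r.last_event_date),
            n_event_days=int(r.n_event_days),
            policy=WindowPolicy(int(r.window_days), Anchoring(r.anchoring)),
        )
        for r in df.itertuples(index=False)
    ]
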