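"""Synthetic patient and claim-stream generator with known ground truth.

Real linked registry–claims data of the kind this package targets is
restricted-access, so every pipeline stage is exercised against simulated
claim streams whose true episode structure is known. The generator emulates
the features that make claims-based SRE measurement hard:

* claims of one clinical episode are *clustered* over a short span of days
  (radiotherapy fractions, surgical follow-up billing), while distinct
  episodes are separated by long gaps;
* pathologic fractures are sometimes *miscoded* with generic "other
  fracture" diagnosis codes, so a specificity-only fracture list
  undercounts them;
* fracture claims are sometimes accompanied by accident/fall E-codes within
  the trauma lookback — either genuine trauma (non-exempt codes) or benign
  same-level falls (exempt).

Each patient draws from an independent deterministic substream derived from
the run seed, so enlarging ``n_patients`` extends the population without
reshuffling existing patients. The calendar is placed in 2000–2010 so the
administrative study-end censor is exercised by default.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .codebook import SREType
from .core import Claim, CodeSystem, DateInterval, Patient, StudyConfig

__all__ = ["SimConfig", "TrueEpisode", "GroundTruth", "generate", "truth_episode_counts"]

_CAL_START = dt.date(2000, 1, 1)
_DX_SPAN_DAYS = 3652  # diagnoses uniform over 2000–2009

# concrete claim codes drawn per subtype; PF has both a specific
# (pathologic-fracture) and a miscoded ("other fracture") variant
_PF_SPECIFIC = ["73310", "73311", "73313", "73314", "73315"]
_PF_OTHER = ["80500", "80700", "81000", "82000", "82100", "82300"]
_SCC_CODES = [("3369", CodeSystem.ICD9_DX), ("63001", CodeSystem.HCPCS)]
_RAD_CODES = [
    ("9224", CodeSystem.ICD9_PX),
    ("77402", CodeSystem.HCPCS),
    ("77414", CodeSystem.HCPCS),
    ("79101", CodeSystem.HCPCS),
]
_BS_CODES = [
    ("8165", CodeSystem.ICD9_PX),
    ("7859", CodeSystem.ICD9_PX),
    ("22521", CodeSystem.HCPCS),
    ("27235", CodeSystem.HCPCS),
]
_TRAUMA_CODES = ["E8120", "E8190", "E8829", "E8840", "E8889"]
_SAME_LEVEL_CODES = ["E8850", "E8859", "E8860"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe a cohort of men aged 66+ with incident metastatic
    prostate cancer: median survival around 1.5 years, radiotherapy and
    fracture the dominant event types, a little under half of patients
    experiencing any SRE over follow-up, and roughly half of true
    pathologic fractures carried on claims as generic "other fracture"
    codes. ``episode_rates`` are marginal episodes per patient-year;
    per-patient risk is multiplied by a gamma frailty (mean 1, shape
    ``frailty_shape``), which concentrates events in a vulnerable minority
    — the overdispersion that makes mean episodes per affected patient far
    exceed the population mean. The realised rate is slightly below the
    nominal one because a minimum inter-episode gap is enforced so that
    ground-truth episodes are well defined.
    """

    n_patients: int = 500
    seed: int = 0
    episode_rates: dict[SREType, float] = field(
        default_factory=lambda: {
            SREType.PF: 0.40,
            SREType.SCC: 0.065,
            SREType.RAD: 0.43,
            SREType.BS: 0.035,
        }
    )
    frailty_shape: float = 0.5
    intra_episode_span_days: tuple[int, int] = (0, 7)
    inter_episode_gap_days: int = 60
    claims_per_episode: tuple[int, int] = (1, 4)
    miscode_prob: float = 0.45
    trauma_co_claim_prob: float = 0.05
    same_level_fall_prob: float = 0.05
    death_median_days: float = 566.0
    well_separated: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        for p in (
            self.miscode_prob,
            self.trauma_co_claim_prob,
            self.same_level_fall_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.well_separated and (
            self.inter_episode_gap_days <= self.intra_episode_span_days[1]
        ):
            raise ValueError(
                "well-separated config requires inter_episode_gap_days > "
                "intra_episode_span_days upper bound"
            )


@dataclass(frozen=True)
class TrueEpisode:
    patient_id: str
    sre_type: SREType
    start: dt.date
    end: dt.date


@dataclass(frozen=True)
class GroundTruth:
    episodes: tuple[TrueEpisode, ...]
    miscoded_claim_ids: frozenset[str]
    trauma_linked_claim_ids: frozenset[str]


def truth_episode_counts(truth: GroundTruth) -> dict[SREType, int]:
    """Tally true episodes per subtype (the recovery target)."""
    counts = {t: 0 for t in SREType}
    for ep in truth.episodes:
        counts[ep.sre_type] += 1
    return counts


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate(config: SimConfig) -> tuple[list[Patient], list[Claim], GroundTruth]:
    """Generate (patients, claims, ground truth); reproducible given the seed."""
    patients: list[Patient] = []
    claims: list[Claim] = []
    episodes: list[TrueEpisode] = []
    miscoded: set[str] = set()
    trauma_linked: set[str] = set()
    death_scale = config.death_median_days / np.log(2.0)

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:06d}"
        dx = _CAL_START + dt.timedelta(days=int(rng.integers(0, _DX_SPAN_DAYS)))
        age = 66 + int(rng.integers(0, 30))
        survival = int(rng.exponential(death_scale)) + 1
        death = dx + dt.timedelta(days=survival)
        death_date = death if death <= config.study.study_end else None
        fu_end = min(death, config.study.study_end)
        enroll = DateInterval(
            dx - dt.timedelta(days=int(rng.integers(400, 800))),
            config.study.study_end + dt.timedelta(days=30),
        )
        patients.append(
            Patient(
                patient_id=pid,
                diagnosis_date=dx,
                age_at_diagnosis=age,
                death_date=death_date,
                ab_enrollment=(enroll,),
            )
        )

        frailty = (
            rng.gamma(config.frailty_shape, 1.0 / config.frailty_shape)
            if config.frailty_shape > 0
            else 1.0
        )
        claim_no = 0
        for sre_type in SREType:
            rate = config.episode_rates.get(sre_type, 0.0) * frailty
            if rate <= 0:
                continue
            mean_extra = 365.0 / rate
            day = dx
            while True:
                gap = config.inter_episode_gap_days + rng.exponential(mean_extra)
                if gap > (fu_end - day).days:
                    break
                day = day + dt.timedelta(days=int(gap))
                claim_no, emitted = _emit_episode(
                    rng, config, pid, sre_type, day, fu_end, claim_no,
                    claims, miscoded, trauma_linked,
                )
                if emitted is not None:
                    episodes.append(emitted)
                # next gap measured from the episode end
                day = emitted.end if emitted is not None else day

    claims.sort(key=lambda c: (c.patient_id, c.service_date, c.claim_id))
    return (
        patients,
        claims,
        GroundTruth(
            episodes=tuple(episodes),
            miscoded_claim_ids=frozenset(miscoded),
            trauma_linked_claim_ids=frozenset(trauma_linked),
        ),
    )


def _emit_episode(
    rng: np.random.Generator,
    config: SimConfig,
    pid: str,
    sre_type: SREType,
    start: dt.date,
    fu_end: dt.date,
    claim_no: int,
    claims: list[Claim],
    miscoded: set[str],
    trauma_linked: set[str],
) -> tuple[int, TrueEpisode | None]:
    lo, hi = config.claims_per_episode
    n_claims = int(rng.integers(lo, hi + 1))
    span_lo, span_hi = config.intra_episode_span_days
    offsets = {0} | {
        int(rng.integers(span_lo, span_hi + 1)) for _ in range(n_claims - 1)
    }
    days = sorted(start + dt.timedelta(days=o) for o in offsets)
    days = [d for d in days if d <= fu_end]
    if not days:
        return claim_no, None

    is_miscoded = sre_type is SREType.PF and rng.random() < config.miscode_prob
    ep_claim_ids: list[str] = []
    for d in days:
        cid = f"{pid}-C{claim_no:05d}"
        claim_no += 1
        code, system = _draw_code(rng, sre_type, is_miscoded)
        claims.append(Claim(cid, pid, d, code, system))
        ep_claim_ids.append(cid)
        if is_miscoded:
            miscoded.add(cid)

    if sre_type is SREType.PF:
        u = rng.random()
        if u < config.trauma_co_claim_prob:
            t_day = days[0] - dt.timedelta(days=int(rng.integers(0, 15)))
            cid = f"{pid}-C{claim_no:05d}"
            claim_no += 1
            claims.append(
                Claim(cid, pid, t_day, str(rng.choice(_TRAUMA_CODES)), CodeSystem.ICD9_DX)
            )
            trauma_linked.update(ep_claim_ids)
        elif u < config.trauma_co_claim_prob + config.same_level_fall_prob:
            t_day = days[0] - dt.timedelta(days=int(rng.integers(0, 15)))
            cid = f"{pid}-C{claim_no:05d}"
            claim_no += 1
            claims.append(
                Claim(cid, pid, t_day, str(rng.choice(_SAME_LEVEL_CODES)), CodeSystem.ICD9_DX)
            )

    return claim_no, TrueEpisode(pid, sre_type, days[0], days[-1])


def _draw_code(
    rng: np.random.Generator, sre_type: SREType, miscoded: bool
) -> tuple[str, CodeSystem]:
    if sre_type is SREType.PF:
        pool = _PF_OTHER if miscoded else _PF_SPECIFIC
        return str(rng.choice(pool)), CodeSystem.ICD9_DX
    pool = {SREType.SCC: _SCC_CODES, SREType.RAD: _RAD_CODES, SREType.BS: _BS_CODES}[
        sre_type
    ]
    code, system = pool[int(rng.integers(0, len(pool)))]
    return code, system
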