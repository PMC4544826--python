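import datetime as dt
import random

import pytest

import skelevent as sk
from skelevent.codebook import SREType, Tier
from skelevent.events import EventStatus

from conftest import make_claim, make_patient


def run_identify(codebook, claims, definition, patients=None):
    patients = patients or [make_patient()]
    cohort = sk.select_cohort(patients, claims, codebook)
    return sk.identify_events(claims, codebook, definition, cohort)


def kept_days(events, sre_type=None):
    return {
        (e.patient_id, e.date)
        for e in sk.kept(events)
        if sre_type is None or e.sre_type is sre_type
    }


class TestTraumaExclusion:
    def test_other_fracture_with_recent_trauma_excluded(self, codebook, base_case):
        claims = [
            make_claim("P1", 100, "821.00"),   # other fracture
            make_claim("P1", 92, "E812.9"),    # motor-vehicle accident 8 days before
        ]
        events = run_identify(codebook, claims, base_case)
        assert [e.status for e in events] == [EventStatus.EXCLUDED_TRAUMA]

    def test_same_level_fall_does_not_exclude(self, codebook, base_case):
        claims = [
            make_claim("P1", 100, "821.00"),
            make_claim("P1", 98, "E885.9"),  # slip/trip on same level: exempt
        ]
        events = run_identify(codebook, claims, base_case)
        assert [e.status for e in events] == [EventStatus.KEPT]

    def test_specific_pathologic_fracture_never_excluded(self, codebook, base_case):
        claims = [
            make_claim("P1", 100, "733.14"),
            make_claim("P1", 92, "E812.9"),
        ]
        events = run_identify(codebook, claims, base_case)
        assert [e.status for e in events] == [EventStatus.KEPT]

    @pytest.mark.parametrize(
        "offset,excluded", [(13, True), (14, True), (15, False), (0, True)]
    )
    def test_lookback_boundary_inclusive(self, codebook, base_case, offset, excluded):
        """Trauma exactly 14 days before (or same day) excludes; 15 days does not."""
        claims = [
            make_claim("P1", 100, "821.00"),
            make_claim("P1", 100 - offset, "E884.0"),
        ]
        events = run_identify(codebook, claims, base_case)
        want = EventStatus.EXCLUDED_TRAUMA if excluded else EventStatus.KEPT
        assert [e.status for e in events] == [want]

    def test_exempt_code_does_not_shield_distinct_trauma(self, codebook, base_case):
        claims = [
            make_claim("P1", 100, "821.00"),
            make_claim("P1", 98, "E885.9"),  # exempt
            make_claim("P1", 95, "E812.9"),  # non-exempt, in window
        ]
        events = run_identify(codebook, claims, base_case)
        assert [e.status for e in events] == [EventStatus.EXCLUDED_TRAUMA]

    def test_adding_trauma_never_adds_kept_events(self, codebook, base_case):
        base = [
            make_claim("P1", 50, "805.00"),
            make_claim("P1", 120, "821.00"),
            make_claim("P1", 200, "733.14"),
        ]
        before = kept_days(run_identify(codebook, base, base_case))
        with_trauma = base + [make_claim("P1", 115, "E888.9")]
        after = kept_days(run_identify(codebook, with_trauma, base_case))
        assert after <= before


class TestDayGranularity:
    def test_same_day_claims_merge_to_one_event(self, codebook, base_case):
        claims = [
            make_claim("P1", 100, "733.14"),
            make_claim("P1", 100, "733.15"),
        ]
        events = run_identify(codebook, claims, base_case)
        assert len(events) == 1
        assert len(events[0].source_claim_ids) == 2

    def test_specific_claim_upgrades_mixed_day(self, codebook, base_case):
        """A day with both 733.1x and other-fracture claims is specificity-tier,
        hence immune to the trauma rule."""
        claims = [
            make_claim("P1", 100, "733.14"),
            make_claim("P1", 100, "821.00"),
            make_claim("P1", 95, "E812.9"),
        ]
        events = run_identify(codebook, claims, base_case)
        assert events[0].matched_tier is Tier.SPECIFICITY
        assert events[0].status is EventStatus.KEPT

    def test_empty_claim_list(self, codebook, base_case):
        assert run_identify(codebook, [], base_case) == []

    def test_outside_followup_flagged(self, codebook, base_case):
        p = make_patient(death=dt.date(2005, 6, 1))
        claims = [make_claim("P1", 200, "733.14")]  # after death
        events = run_identify(codebook, claims, base_case, [p])
        assert [e.status for e in events] == [EventStatus.EXCLUDED_OUTSIDE_FOLLOWUP]


class TestSameDayHierarchy:
    def test_rad_excluded_when_enabled(self, codebook):
        d = sk.make_definition("base_case", same_day_hierarchy=True)
        claims = [
            make_claim("P1", 100, "733.14"),
            make_claim("P1", 100, "9224", sk.CodeSystem.ICD9_PX),
        ]
        events = run_identify(codebook, claims, d)
        statuses = {e.sre_type: e.status for e in events}
        assert statuses[SREType.PF] is EventStatus.KEPT
        assert statuses[SREType.RAD] is EventStatus.EXCLUDED_HIERARCHY

    def test_both_kept_when_disabled(self, codebook, base_case):
        claims = [
            make_claim("P1", 100, "733.14"),
            make_claim("P1", 100, "9224", sk.CodeSystem.ICD9_PX),
        ]
        events = run_identify(codebook, claims, base_case)
        assert all(e.status is EventStatus.KEPT for e in events)

    def test_rad_alone_kept_when_enabled(self, codebook):
        d = sk.make_definition("base_case", same_day_hierarchy=True)
        claims = [make_claim("P1", 100, "9224", sk.CodeSystem.ICD9_PX)]
        events = run_identify(codebook, claims, d)
        assert [e.status for e in events] == [EventStatus.KEPT]


class TestOptionalVariants:
    def test_rad_concurrency_filter(self, codebook):
        d = sk.make_definition("base_case", rad_concurrency_filter=True)
        claims = [
            make_claim("P1", 100, "9224", sk.CodeSystem.ICD9_PX),  # no context
            make_claim("P1", 150, "9224", sk.CodeSystem.ICD9_PX),
            make_claim("P1", 150, "198.5"),  # bone metastasis same day
        ]
        events = run_identify(codebook, claims, d)
        by_day = {e.date: e.status for e in events if e.sre_type is SREType.RAD}
        days = sorted(by_day)
        assert by_day[days[0]] is EventStatus.EXCLUDED_CONCURRENCY
        assert by_day[days[1]] is EventStatus.KEPT

    def test_bs_trauma_lookback(self, codebook):
        d = sk.make_definition("base_case", bs_trauma_lookback=True)
        claims = [
            make_claim("P1", 100, "8165", sk.CodeSystem.ICD9_PX),
            make_claim("P1", 95, "E812.9"),
        ]
        events = run_identify(codebook, claims, d)
        assert [e.status for e in events] == [EventStatus.EXCLUDED_TRAUMA]


class TestDefinitionMonotonicity:
    def make_mixed_claims(self, rng):
        codes = [
            ("733.14", sk.CodeSystem.ICD9_DX),  # PF specific
            ("821.00", sk.CodeSystem.ICD9_DX),  # PF other-fracture
            ("336.9", sk.CodeSystem.ICD9_DX),   # SCC specific
            ("722.70", sk.CodeSystem.ICD9_DX),  # SCC myelopathy (ext)
            ("9224", sk.CodeSystem.ICD9_PX),    # RAD 2D/3D
            ("77418", sk.CodeSystem.HCPCS),     # RAD IMRT (ext)
            ("8165", sk.CodeSystem.ICD9_PX),    # BS
            ("E812.9", sk.CodeSystem.ICD9_DX),  # trauma
        ]
        return [
            make_claim("P1", rng.randrange(0, 1000), code, system)
            for code, system in rng.choices(codes, k=60)
        ]

    def test_tier_direction_per_subtype(self, codebook, base_case, alternative):
        """Base-case PF ⊇ alternative PF; alternative SCC/RAD ⊇ base-case; BS equal."""
        rng = random.Random(42)
        for _ in range(10):
            claims = self.make_mixed_claims(rng)
            ev_base = run_identify(codebook, claims, base_case)
            ev_alt = run_identify(codebook, claims, alternative)
            assert kept_days(ev_base, SREType.PF) >= kept_days(ev_alt, SREType.PF)
            assert kept_days(ev_alt, SREType.SCC) >= kept_days(ev_base, SREType.SCC)
            assert kept_days(ev_alt, SREType.RAD) >= kept_days(ev_base, SREType.RAD)
            assert kept_days(ev_base, SREType.BS) == kept_days(ev_alt, SREType.BS)

    def test_order_independence(self, codebook, base_case):
        rng = random.Random(7)
        claims = self.make_mixed_claims(rng)
        events_fwd = run_identify(codebook, claims, base_case)
        shuffled = claims[:]
        rng.shuffle(shuffled)
        events_shuf = run_identify(codebook, shuffled, base_case)
        assert events_fwd == events_shuf
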