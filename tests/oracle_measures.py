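"""Independent brute-force evaluator for the 14 measure emulations.

Deliberately written as one literal hand-coded function per measure (no
shared declarative machinery) so it can serve as an oracle for the
catalog-driven engine.  Any change to the engine's semantics must be made
here *independently* from the catalog.
"""

from __future__ import annotations

import calendar
from datetime import date, timedelta

from fragqm.measures import MeasurementPeriod, Outcome
from fragqm.records import ClinicalEvent, EventType, PatientDemographics


def _age(birth: date, anchor: date) -> int:
    years = anchor.year - birth.year
    bm, bd = birth.month, birth.day
    if bm == 2 and bd == 29 and not calendar.isleap(anchor.year):
        bd = 28
    if (anchor.month, anchor.day) < (bm, bd):
        years -= 1
    return years


def _months_before(d: date, months: int) -> date:
    m = d.month - 1 - months
    y = d.year + m // 12
    mo = m % 12 + 1
    return date(y, mo, min(d.day, calendar.monthrange(y, mo)[1]))


def _dx(events, concepts, on_or_before, not_before=None):
    for e in events:
        if e.event_type is EventType.DIAGNOSIS and e.concept in concepts:
            if e.event_date <= on_or_before and (not_before is None or e.event_date >= not_before):
                return True
    return False


def _any(events, concepts, lo=None, hi=None):
    for e in events:
        if e.concept in concepts:
            if (lo is None or e.event_date >= lo) and (hi is None or e.event_date <= hi):
                return True
    return False


def _encounter_in_period(events, period):
    return any(
        e.event_type is EventType.ENCOUNTER and period.start <= e.event_date <= period.end
        for e in events
    )


def _latest(events, concept, lo, hi):
    cands = [e for e in events if e.concept == concept and lo <= e.event_date <= hi]
    if not cands:
        return None
    return max(cands, key=lambda e: (e.event_date, e.concept, e.value or 0.0, e.value2 or 0.0))


def _diabetes_denominator(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if not (18 <= a <= 75):
        return False
    if not _dx(events, {"diabetes"}, period.end, _months_before(period.end, 24)):
        return False
    return _encounter_in_period(events, period)


def _hospice_excluded(events, period):
    return _any(events, {"hospice_care"}, period.start, period.end)


def cms122(p, events, period):
    if not _diabetes_denominator(p, events, period):
        return Outcome.NOT_APPLICABLE
    if _hospice_excluded(events, period):
        return Outcome.EXCLUDED
    latest = _latest(events, "hba1c", period.start, period.end)
    if latest is None:
        poor = True  # no result at all counts as poor control
    else:
        poor = latest.value is not None and latest.value > 9.0
    return Outcome.NONCOMPLIANT if poor else Outcome.COMPLIANT


def cms131(p, events, period):
    if not _diabetes_denominator(p, events, period):
        return Outcome.NOT_APPLICABLE
    if _hospice_excluded(events, period):
        return Outcome.EXCLUDED
    met = _any(events, {"retinal_exam"}, _months_before(period.start, 12), period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms123(p, events, period):
    if not _diabetes_denominator(p, events, period):
        return Outcome.NOT_APPLICABLE
    if _hospice_excluded(events, period):
        return Outcome.EXCLUDED
    met = _any(events, {"foot_exam"}, period.start, period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms134(p, events, period):
    if not _diabetes_denominator(p, events, period):
        return Outcome.NOT_APPLICABLE
    if _hospice_excluded(events, period):
        return Outcome.EXCLUDED
    met = (
        _any(events, {"nephropathy_screening"}, period.start, period.end)
        or _any(events, {"ace_arb"}, period.start, period.end)
        or any(
            e.event_type is EventType.DIAGNOSIS
            and e.concept == "nephropathy"
            and period.start <= e.event_date <= period.end
            for e in events
        )
    )
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms165(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    mid = period.start + (period.end - period.start) / 2
    if not (18 <= a <= 85):
        return Outcome.NOT_APPLICABLE
    if not _dx(events, {"hypertension"}, mid):
        return Outcome.NOT_APPLICABLE
    if not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if _any(events, {"esrd"}, None, period.end) or _any(
        events, {"pregnancy"}, period.start, period.end
    ):
        return Outcome.EXCLUDED
    latest = _latest(events, "bp_reading", period.start, period.end)
    ok = (
        latest is not None
        and latest.value is not None
        and latest.value2 is not None
        and latest.value < 140
        and latest.value2 < 90
    )
    return Outcome.COMPLIANT if ok else Outcome.NONCOMPLIANT


def cms125(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if p.sex != "female" or not (51 <= a <= 74) or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if _any(events, {"bilateral_mastectomy"}, None, period.end):
        return Outcome.EXCLUDED
    met = _any(events, {"mammogram"}, _months_before(period.end, 27), period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms124(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if p.sex != "female" or not (23 <= a <= 64) or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if _any(events, {"hysterectomy"}, None, period.end):
        return Outcome.EXCLUDED
    met = _any(events, {"cervical_cytology"}, _months_before(period.end, 36), period.end)
    if not met and a >= 30:
        met = _any(events, {"hpv_test"}, _months_before(period.end, 60), period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms130(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if not (50 <= a <= 75) or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if _any(events, {"total_colectomy"}, None, period.end) or _any(
        events, {"colorectal_cancer"}, None, period.end
    ):
        return Outcome.EXCLUDED
    met = (
        _any(events, {"fobt"}, period.start, period.end)
        or _any(events, {"sigmoidoscopy"}, _months_before(period.end, 60), period.end)
        or _any(events, {"colonoscopy"}, _months_before(period.end, 120), period.end)
    )
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms127(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if a < 65 or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    met = _any(events, {"pneumococcal_vaccination"}, None, period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms153(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if p.sex != "female" or not (16 <= a <= 24) or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if not _any(events, {"sexual_activity"}, period.start, period.end):
        return Outcome.NOT_APPLICABLE
    met = _any(events, {"chlamydia_test"}, period.start, period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms155(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if not (3 <= a <= 17) or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if _any(events, {"pregnancy"}, period.start, period.end):
        return Outcome.EXCLUDED
    met = _any(events, {"bmi_percentile"}, period.start, period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


def cms146(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if not (3 <= a <= 18):
        return Outcome.NOT_APPLICABLE
    meds = sorted(e.event_date for e in events if e.concept == "antibiotic")
    tests = sorted(e.event_date for e in events if e.concept == "strep_test")
    episodes, excluded = [], 0
    for e in events:
        if e.concept != "pharyngitis" or not (period.start <= e.event_date <= period.end):
            continue
        if not any(timedelta(0) <= m - e.event_date <= timedelta(days=3) for m in meds):
            continue
        if any(timedelta(0) < e.event_date - m <= timedelta(days=30) for m in meds):
            excluded += 1
        else:
            episodes.append(e.event_date)
    if not episodes:
        return Outcome.EXCLUDED if excluded else Outcome.NOT_APPLICABLE
    for idx in episodes:
        if not any(abs((t - idx).days) <= 3 for t in tests):
            return Outcome.NONCOMPLIANT
    return Outcome.COMPLIANT


def cms156(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if a < 65 or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    if _hospice_excluded(events, period):
        return Outcome.EXCLUDED
    used = _any(events, {"high_risk_medication"}, period.start, period.end)
    return Outcome.NONCOMPLIANT if used else Outcome.COMPLIANT


def cms74(p, events, period):
    a = _age(p.birth_date, period.end) if p.birth_date <= period.end else -1
    if not (0 <= a <= 20) or not _encounter_in_period(events, period):
        return Outcome.NOT_APPLICABLE
    met = _any(events, {"fluoride_varnish"}, period.start, period.end)
    return Outcome.COMPLIANT if met else Outcome.NONCOMPLIANT


ORACLES = {
    "cms122": cms122,
    "cms131": cms131,
    "cms123": cms123,
    "cms134": cms134,
    "cms165": cms165,
    "cms125": cms125,
    "cms124": cms124,
    "cms130": cms130,
    "cms127": cms127,
    "cms153": cms153,
    "cms155": cms155,
    "cms146": cms146,
    "cms156": cms156,
    "cms74": cms74,
}
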