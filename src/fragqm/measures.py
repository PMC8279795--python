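"""Declarative mini-engine for ambulatory electronic clinical quality measures.

Each measure is a simplified emulation of a MIPS-reportable ambulatory eCQM:
it preserves the structural drivers of cross-facility discrepancy — age/sex
gates, diagnosis-dependent denominators, qualifying-encounter requirements,
lookback windows, exclusions, value thresholds and inverse logic — without the
licensed value sets or CQL of the official specifications.  A patient
evaluates to one of four outcomes per measure:

``NOT_APPLICABLE``
    denominator (eligibility) criteria not met;
``EXCLUDED``
    eligible but an exclusion criterion applies;
``NONCOMPLIANT`` / ``COMPLIANT``
    eligible, not excluded; compliant represents recommended care.  For
    *inverse* measures (poor HbA1c control, high-risk medication use) the raw
    numerator is undesirable, so a met raw numerator maps to NONCOMPLIANT.

Eligibility is purely existential — it depends only on the presence of
events, never their absence — which makes it monotone under data aggregation:
adding external-facility data can only move a patient out of NOT_APPLICABLE,
never into it.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date
from enum import Enum
from importlib import resources
from typing import Callable, Sequence

import yaml

from .records import ClinicalEvent, EventType, PatientDemographics

__all__ = [
    "Outcome",
    "MeasurementPeriod",
    "MeasureDefinition",
    "age_on",
    "resolve_denominator",
    "resolve_exclusion",
    "resolve_numerator",
    "evaluate_measure",
    "load_catalog",
    "load_concept_registry",
]


class Outcome(str, Enum):
    NOT_APPLICABLE = "NOT_APPLICABLE"
    EXCLUDED = "EXCLUDED"
    NONCOMPLIANT = "NONCOMPLIANT"
    COMPLIANT = "COMPLIANT"


@dataclass(frozen=True)
class MeasurementPeriod:
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("measurement period start must not follow end")

    @property
    def mid(self) -> date:
        return self.start + (self.end - self.start) / 2

    @classmethod
    def calendar_year(cls, year: int) -> "MeasurementPeriod":
        return cls(date(year, 1, 1), date(year, 12, 31))

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


def _months_before(d: date, months: int) -> date:
    """The calendar date ``months`` months before ``d`` (day clamped)."""
    m = d.month - 1 - months
    year = d.year + m // 12
    month = m % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def age_on(birth_date: date, anchor: date) -> int:
    """Completed years of age on ``anchor``.

    A Feb-29 birthday completes a year on Feb-28 in non-leap years.
    """
    if anchor < birth_date:
        raise ValueError("anchor date precedes birth date")
    years = anchor.year - birth_date.year
    bmonth, bday = birth_date.month, birth_date.day
    if bmonth == 2 and bday == 29 and not calendar.isleap(anchor.year):
        bday = 28
    if (anchor.month, anchor.day) < (bmonth, bday):
        years -= 1
    return years


# --- windows -----------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """A closed time window anchored to the measurement period.

    kinds: ``period`` (within the period), ``ever`` (on/before period end),
    ``before_end_months`` (within N months ending at period end),
    ``period_plus_months`` (period extended N months earlier).
    """

    kind: str
    months: int | None = None

    def contains(self, d: date, period: MeasurementPeriod) -> bool:
        if self.kind == "period":
            return period.contains(d)
        if self.kind == "ever":
            return d <= period.end
        if self.kind == "before_end_months":
            return _months_before(period.end, self.months) <= d <= period.end
        if self.kind == "period_plus_months":
            return _months_before(period.start, self.months) <= d <= period.end
        raise ValueError(f"unknown window kind {self.kind!r}")


# value predicates applied to the most recent qualifying observation
_VALUE_TESTS: dict[str, Callable[[ClinicalEvent], bool]] = {
    # HbA1c above the poor-control threshold (percent)
    "hba1c_gt_9": lambda e: e.value is not None and e.value > 9.0,
    # systolic < 140 mm Hg AND diastolic < 90 mm Hg
    "bp_controlled": lambda e: (
        e.value is not None and e.value2 is not None and e.value < 140 and e.value2 < 90
    ),
}


@dataclass(frozen=True)
class ConditionRequirement:
    """Denominator diagnosis: ≥1 matching diagnosis event on/before the anchor."""

    concepts: frozenset[str]
    anchor: str = "period_end"  # or "period_mid"
    lookback_months: int | None = None

    def satisfied(self, events: Sequence[ClinicalEvent], period: MeasurementPeriod) -> bool:
        anchor = period.end if self.anchor == "period_end" else period.mid
        lo = _months_before(anchor, self.lookback_months) if self.lookback_months else None
        for e in events:
            if e.event_type is not EventType.DIAGNOSIS or e.concept not in self.concepts:
                continue
            if e.event_date <= anchor and (lo is None or e.event_date >= lo):
                return True
        return False


@dataclass(frozen=True)
class ExclusionRule:
    concepts: frozenset[str]
    window: Window

    def applies(self, events: Sequence[ClinicalEvent], period: MeasurementPeriod) -> bool:
        return any(
            e.concept in self.concepts and self.window.contains(e.event_date, period)
            for e in events
        )


@dataclass(frozen=True)
class NumeratorRule:
    concepts: frozenset[str]
    window: Window
    value_test: str | None = None
    met_if_absent: bool = False  # value measures: outcome when no observation exists
    min_age: int | None = None  # rule applies only from this age (e.g. HPV co-testing)

    def met(
        self,
        events: Sequence[ClinicalEvent],
        period: MeasurementPeriod,
        patient_age: int,
    ) -> bool:
        if self.min_age is not None and patient_age < self.min_age:
            return False
        qualifying = [
            e
            for e in events
            if e.concept in self.concepts and self.window.contains(e.event_date, period)
        ]
        if self.value_test is None:
            return bool(qualifying)
        if not qualifying:
            return self.met_if_absent
        # most recent observation wins; same-date ties broken by a stable
        # (concept, value, value2) ordering so evaluation is deterministic
        latest = max(
            qualifying,
            key=lambda e: (e.event_date, e.concept, e.value or 0.0, e.value2 or 0.0),
        )
        return _VALUE_TESTS[self.value_test](latest)


@dataclass(frozen=True)
class EpisodeSpec:
    """Episode-of-care logic for the pharyngitis testing measure."""

    index_concepts: frozenset[str]
    med_concepts: frozenset[str]
    med_within_days: int
    prior_med_exclusion_days: int
    test_concepts: frozenset[str]
    test_within_days: int


@dataclass(frozen=True)
class MeasureDefinition:
    measure_id: str
    description: str
    sex_restriction: str | None = None
    age_min: int | None = None
    age_max: int | None = None
    age_anchor: str = "period_end"
    conditions: tuple[ConditionRequirement, ...] = ()
    requires_encounter: bool = True
    required_markers: tuple[frozenset[str], ...] = ()
    exclusions: tuple[ExclusionRule, ...] = ()
    numerator: tuple[NumeratorRule, ...] = ()
    inverse: bool = False
    episodic: bool = False
    episode: EpisodeSpec | None = None

    def __post_init__(self) -> None:
        if self.age_min is not None and self.age_max is not None and self.age_min > self.age_max:
            raise ValueError(f"{self.measure_id}: age_min > age_max")
        if self.episodic and self.episode is None:
            raise ValueError(f"{self.measure_id}: episodic measure needs an episode spec")

    def _anchor_date(self, period: MeasurementPeriod) -> date:
        return period.end if self.age_anchor == "period_end" else period.start


# --- resolution --------------------------------------------------------------

def _patient_age(defn: MeasureDefinition, patient: PatientDemographics, period: MeasurementPeriod) -> int:
    anchor = defn._anchor_date(period)
    if patient.birth_date > anchor:
        return -1
    return age_on(patient.birth_date, anchor)


def resolve_denominator(
    defn: MeasureDefinition,
    patient: PatientDemographics,
    events: Sequence[ClinicalEvent],
    period: MeasurementPeriod,
) -> bool:
    """Denominator (eligibility) logic; existential only."""
    if defn.sex_restriction is not None and patient.sex != defn.sex_restriction:
        return False
    age = _patient_age(defn, patient, period)
    if defn.age_min is not None and age < defn.age_min:
        return False
    if defn.age_max is not None and age > defn.age_max:
        return False
    if age < 0:
        return False
    for cond in defn.conditions:
        if not cond.satisfied(events, period):
            return False
    if defn.requires_encounter:
        if not any(
            e.event_type is EventType.ENCOUNTER and period.contains(e.event_date)
            for e in events
        ):
            return False
    for marker in defn.required_markers:
        if not any(e.concept in marker and period.contains(e.event_date) for e in events):
            return False
    return True


def resolve_exclusion(
    defn: MeasureDefinition,
    patient: PatientDemographics,
    events: Sequence[ClinicalEvent],
    period: MeasurementPeriod,
) -> bool:
    return any(rule.applies(events, period) for rule in defn.exclusions)


def resolve_numerator(
    defn: MeasureDefinition,
    patient: PatientDemographics,
    events: Sequence[ClinicalEvent],
    period: MeasurementPeriod,
) -> bool:
    age = _patient_age(defn, patient, period)
    return any(rule.met(events, period, age) for rule in defn.numerator)


def _evaluate_episodic(
    defn: MeasureDefinition,
    patient: PatientDemographics,
    events: Sequence[ClinicalEvent],
    period: MeasurementPeriod,
) -> Outcome:
    """Episode-of-care evaluation (pharyngitis antibiotic-testing measure).

    An episode is an in-period pharyngitis diagnosis followed by an antibiotic
    within ``med_within_days``.  Episodes with an antibiotic in the preceding
    ``prior_med_exclusion_days`` are excluded.  The patient is COMPLIANT iff
    every remaining episode has a rapid strep test within ``test_within_days``
    of the index diagnosis.
    """
    spec = defn.episode
    assert spec is not None
    if defn.sex_restriction is not None and patient.sex != defn.sex_restriction:
        return Outcome.NOT_APPLICABLE
    age = _patient_age(defn, patient, period)
    if age < (defn.age_min or 0) or (defn.age_max is not None and age > defn.age_max):
        return Outcome.NOT_APPLICABLE

    med_dates = sorted(e.event_date for e in events if e.concept in spec.med_concepts)
    test_dates = sorted(e.event_date for e in events if e.concept in spec.test_concepts)

    episodes: list[date] = []
    excluded_episodes = 0
    for e in events:
        if e.concept not in spec.index_concepts or not period.contains(e.event_date):
            continue
        has_med = any(
            0 <= (m - e.event_date).days <= spec.med_within_days for m in med_dates
        )
        if not has_med:
            continue
        prior_med = any(
            0 < (e.event_date - m).days <= spec.prior_med_exclusion_days for m in med_dates
        )
        if prior_med:
            excluded_episodes += 1
        else:
            episodes.append(e.event_date)

    if not episodes:
        return Outcome.EXCLUDED if excluded_episodes else Outcome.NOT_APPLICABLE
    for idx in episodes:
        tested = any(abs((t - idx).days) <= spec.test_within_days for t in test_dates)
        if not tested:
            return Outcome.NONCOMPLIANT
    return Outcome.COMPLIANT


def evaluate_measure(
    defn: MeasureDefinition,
    patient: PatientDemographics,
    events: Sequence[ClinicalEvent],
    period: MeasurementPeriod,
) -> Outcome:
    """Evaluate one measure for one patient to its four-state outcome.

    Precedence is strict: eligibility, then exclusion, then numerator; the
    compliant/noncompliant mapping is flipped for inverse measures.
    """
    if defn.episodic:
        return _evaluate_episodic(defn, patient, events, period)
    if not resolve_denominator(defn, patient, events, period):
        return Outcome.NOT_APPLICABLE
    if resolve_exclusion(defn, patient, events, period):
        return Outcome.EXCLUDED
    raw = resolve_numerator(defn, patient, events, period)
    compliant = raw != defn.inverse
    return Outcome.COMPLIANT if compliant else Outcome.NONCOMPLIANT


# --- catalog loading ----------------------------------------------------------

def _parse_window(d: dict) -> Window:
    return Window(kind=d["kind"], months=d.get("months"))


def _parse_measure(d: dict) -> MeasureDefinition:
    age = d.get("age", {})
    episode = None
    if d.get("episode"):
        ep = d["episode"]
        episode = EpisodeSpec(
            index_concepts=frozenset(ep["index_concepts"]),
            med_concepts=frozenset(ep["med_concepts"]),
            med_within_days=ep["med_within_days"],
            prior_med_exclusion_days=ep["prior_med_exclusion_days"],
            test_concepts=frozenset(ep["test_concepts"]),
            test_within_days=ep["test_within_days"],
        )
    return MeasureDefinition(
        measure_id=d["id"],
        description=d["description"],
        sex_restriction=d.get("sex"),
        age_min=age.get("min"),
        age_max=age.get("max"),
        age_anchor=d.get("age_anchor", "period_end"),
        conditions=tuple(
            ConditionRequirement(
                concepts=frozenset(c["concepts"]),
                anchor=c.get("anchor", "period_end"),
                lookback_months=c.get("lookback_months"),
            )
            for c in d.get("conditions", [])
        ),
        requires_encounter=d.get("requires_encounter", True),
        required_markers=tuple(frozenset(m) for m in d.get("required_markers", [])),
        exclusions=tuple(
            ExclusionRule(concepts=frozenset(x["concepts"]), window=_parse_window(x["window"]))
            for x in d.get("exclusions", [])
        ),
        numerator=tuple(
            NumeratorRule(
                concepts=frozenset(n["concepts"]),
                window=_parse_window(n["window"]),
                value_test=n.get("value_test"),
                met_if_absent=n.get("met_if_absent", False),
                min_age=n.get("min_age"),
            )
            for n in d.get("numerator", [])
        ),
        inverse=d.get("inverse", False),
        episodic=d.get("episodic", False),
        episode=episode,
    )


def load_catalog(path: str | None = None) -> list[MeasureDefinition]:
    """Load the measure catalog (the packaged 14-measure file by default)."""
    if path is None:
        text = resources.files("fragqm.data").joinpath("measure_catalog.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    defs = [_parse_measure(d) for d in raw["measures"]]
    ids = [m.measure_id for m in defs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate measure ids in catalog")
    return defs


def load_concept_registry() -> "list[dict]":
    """Illustrative code→concept rows shipped for ingest testing."""
    import csv
    import io

    text = resources.files("fragqm.data").joinpath("concept_registry.csv").read_text()
    return list(csv.DictReader(io.StringIO(text)))
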