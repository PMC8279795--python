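"""Measure engine: age arithmetic, the four-state outcome logic, and
equivalence with an independently hand-coded evaluator."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragqm.measures import (
    Outcome,
    age_on,
    evaluate_measure,
    load_concept_registry,
    resolve_denominator,
    resolve_exclusion,
    resolve_numerator,
)
from fragqm.records import EventType

from conftest import CONCEPT_TYPES, encounter, ev, make_patient, random_patient_and_events
from oracle_measures import ORACLES


class TestAgeOn:
    @pytest.mark.parametrize(
        "birth, anchor, expected",
        [
            (date(2000, 1, 1), date(2018, 6, 1), 18),
            (date(2000, 7, 1), date(2018, 6, 30), 17),  # birthday not yet reached
            (date(2000, 2, 29), date(2018, 2, 28), 18),  # leap birthday completes Feb 28
            (date(2000, 2, 29), date(2020, 2, 28), 19),  # ...but not in leap years
            (date(2000, 5, 5), date(2000, 5, 5), 0),
        ],
    )
    def test_completed_years(self, birth, anchor, expected):
        assert age_on(birth, anchor) == expected

    def test_anchor_before_birth_errors(self):
        with pytest.raises(ValueError):
            age_on(date(2000, 1, 2), date(2000, 1, 1))


def _dx(concept, d):
    return ev(concept, d, EventType.DIAGNOSIS)


class TestDenominator:
    def test_elderly_with_encounter_eligible_for_pneumococcal(self, catalog_by_id, period):
        p = make_patient(sex="male", birth_date=date(1950, 1, 1))
        assert resolve_denominator(catalog_by_id["cms127"], p, [encounter()], period)

    def test_sex_restriction_blocks_breast_screening(self, catalog_by_id, period):
        p = make_patient(sex="male", birth_date=date(1958, 1, 1))
        assert not resolve_denominator(catalog_by_id["cms125"], p, [encounter()], period)

    def test_diabetes_without_period_encounter_not_eligible(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1958, 1, 1))
        events = [_dx("diabetes", date(2017, 5, 1))]
        assert not resolve_denominator(catalog_by_id["cms122"], p, events, period)
        assert resolve_denominator(catalog_by_id["cms122"], p, events + [encounter()], period)

    def test_stale_diabetes_diagnosis_outside_recency_window(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1958, 1, 1))
        events = [_dx("diabetes", date(2014, 5, 1)), encounter()]
        assert not resolve_denominator(catalog_by_id["cms122"], p, events, period)


class TestExclusion:
    def test_hysterectomy_ever_excludes_cervical_screening(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1980, 1, 1))
        events = [encounter(), ev("hysterectomy", date(2005, 1, 1))]
        assert resolve_exclusion(catalog_by_id["cms124"], p, events, period)
        assert evaluate_measure(catalog_by_id["cms124"], p, events, period) is Outcome.EXCLUDED

    def test_no_exclusion_events(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1980, 1, 1))
        assert not resolve_exclusion(catalog_by_id["cms124"], p, [encounter()], period)

    def test_in_period_pregnancy_excludes_pediatric_bmi(self, catalog_by_id, period):
        p = make_patient(birth_date=date(2003, 1, 1))  # 15 at period end
        events = [encounter(), _dx("pregnancy", date(2018, 7, 1))]
        assert evaluate_measure(catalog_by_id["cms155"], p, events, period) is Outcome.EXCLUDED

    def test_pre_period_pregnancy_does_not_exclude(self, catalog_by_id, period):
        p = make_patient(birth_date=date(2003, 1, 1))
        events = [encounter(), _dx("pregnancy", date(2017, 7, 1))]
        assert evaluate_measure(catalog_by_id["cms155"], p, events, period) is Outcome.NONCOMPLIANT


class TestNumerator:
    def test_colonoscopy_ten_year_window(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1955, 1, 1))
        events = [encounter(), ev("colonoscopy", date(2011, 6, 1))]
        assert resolve_numerator(catalog_by_id["cms130"], p, events, period)
        stale = [encounter(), ev("colonoscopy", date(2007, 6, 1))]
        assert not resolve_numerator(catalog_by_id["cms130"], p, stale, period)

    def test_bp_most_recent_reading_decides(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1960, 1, 1))
        events = [
            encounter(),
            _dx("hypertension", date(2017, 1, 1)),
            ev("bp_reading", date(2018, 3, 1), EventType.VITAL_SIGN, value=150, value2=95),
            ev("bp_reading", date(2018, 11, 1), EventType.VITAL_SIGN, value=132, value2=84),
        ]
        assert evaluate_measure(catalog_by_id["cms165"], p, events, period) is Outcome.COMPLIANT
        # drop the later controlled reading: most recent is uncontrolled
        assert (
            evaluate_measure(catalog_by_id["cms165"], p, events[:-1], period)
            is Outcome.NONCOMPLIANT
        )

    def test_hba1c_above_nine_is_poor_control(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1958, 1, 1))
        base = [encounter(), _dx("diabetes", date(2017, 5, 1))]
        high = base + [ev("hba1c", date(2018, 6, 1), EventType.LABORATORY, value=9.5)]
        assert resolve_numerator(catalog_by_id["cms122"], p, high, period)  # raw = poor
        assert evaluate_measure(catalog_by_id["cms122"], p, high, period) is Outcome.NONCOMPLIANT
        # no HbA1c at all is also raw-met (poor control) for this inverse measure
        assert evaluate_measure(catalog_by_id["cms122"], p, base, period) is Outcome.NONCOMPLIANT
        good = base + [ev("hba1c", date(2018, 6, 1), EventType.LABORATORY, value=7.0)]
        assert evaluate_measure(catalog_by_id["cms122"], p, good, period) is Outcome.COMPLIANT

    def test_hpv_rule_requires_age_thirty(self, catalog_by_id, period):
        events = [encounter(), ev("hpv_test", date(2015, 6, 1))]
        young = make_patient(birth_date=date(1991, 1, 1))  # 27
        older = make_patient(birth_date=date(1980, 1, 1))  # 38
        assert evaluate_measure(catalog_by_id["cms124"], young, events, period) is Outcome.NONCOMPLIANT
        assert evaluate_measure(catalog_by_id["cms124"], older, events, period) is Outcome.COMPLIANT


class TestEvaluate:
    def test_high_risk_medication_inverse_mapping(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1948, 1, 1))
        events = [encounter(), ev("high_risk_medication", date(2018, 6, 1), EventType.MEDICATION)]
        assert evaluate_measure(catalog_by_id["cms156"], p, events, period) is Outcome.NONCOMPLIANT
        assert evaluate_measure(catalog_by_id["cms156"], p, [encounter()], period) is Outcome.COMPLIANT

    def test_vaccination_ever_window(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1950, 1, 1))
        events = [encounter(), ev("pneumococcal_vaccination", date(2010, 5, 5), EventType.IMMUNIZATION)]
        assert evaluate_measure(catalog_by_id["cms127"], p, events, period) is Outcome.COMPLIANT

    def test_pharyngitis_episode_logic(self, catalog_by_id, period):
        p = make_patient(birth_date=date(2008, 1, 1))  # 10 years old
        episode = [
            encounter(date(2018, 4, 2)),
            _dx("pharyngitis", date(2018, 4, 2)),
            ev("antibiotic", date(2018, 4, 3), EventType.MEDICATION),
        ]
        tested = episode + [ev("strep_test", date(2018, 4, 2), EventType.LABORATORY, value=1.0)]
        assert evaluate_measure(catalog_by_id["cms146"], p, tested, period) is Outcome.COMPLIANT
        assert evaluate_measure(catalog_by_id["cms146"], p, episode, period) is Outcome.NONCOMPLIANT
        # antibiotic within the prior 30 days excludes the episode
        prior = episode + [ev("antibiotic", date(2018, 3, 20), EventType.MEDICATION)]
        assert evaluate_measure(catalog_by_id["cms146"], p, prior, period) is Outcome.EXCLUDED
        # pharyngitis without a follow-up antibiotic is no episode at all
        no_med = [encounter(date(2018, 4, 2)), _dx("pharyngitis", date(2018, 4, 2))]
        assert evaluate_measure(catalog_by_id["cms146"], p, no_med, period) is Outcome.NOT_APPLICABLE

    def test_precedence_exclusion_beats_numerator(self, catalog_by_id, period):
        p = make_patient(birth_date=date(1960, 1, 1))
        events = [
            encounter(),
            ev("mammogram", date(2018, 2, 1)),
            ev("bilateral_mastectomy", date(2000, 1, 1)),
        ]
        assert evaluate_measure(catalog_by_id["cms125"], p, events, period) is Outcome.EXCLUDED


class TestEngineProperties:
    def test_outcomes_match_independent_oracle_on_random_patients(self, catalog, period):
        """Catalog-driven engine vs literal hand-coded evaluator, 300 random
        patients x 14 measures (the full-size sweep runs in the acceptance
        suite)."""
        rng = np.random.default_rng(2024)
        for i in range(300):
            patient, events = random_patient_and_events(rng, f"P{i}")
            for defn in catalog:
                got = evaluate_measure(defn, patient, events, period)
                want = ORACLES[defn.measure_id](patient, events, period)
                assert got is want, (defn.measure_id, patient, events)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 10))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_eligibility_monotone_under_event_supersets(self, catalog, period, seed, n_extra):
        """Adding events never turns an eligible patient NOT_APPLICABLE."""
        rng = np.random.default_rng(seed)
        patient, events = random_patient_and_events(rng, "PX")
        _, extra = random_patient_and_events(rng, "PX")
        superset = events + extra[:n_extra]
        for defn in catalog:
            before = evaluate_measure(defn, patient, events, period)
            after = evaluate_measure(defn, patient, superset, period)
            if before is not Outcome.NOT_APPLICABLE:
                assert after is not Outcome.NOT_APPLICABLE, defn.measure_id

    def test_inverse_involution(self, catalog, period):
        """Flipping the raw numerator flips COMPLIANT and NONCOMPLIANT for
        direct and inverse measures alike."""
        rng = np.random.default_rng(7)
        checked = 0
        for i in range(400):
            patient, events = random_patient_and_events(rng, f"P{i}")
            # guarantee an in-period encounter so eligibility is frequently met
            events = events + [encounter(date(2018, 6, 1), patient_id=patient.patient_id)]
            for defn in catalog:
                if defn.episodic:
                    continue
                from fragqm.measures import resolve_denominator, resolve_exclusion, resolve_numerator

                if not resolve_denominator(defn, patient, events, period):
                    continue
                if resolve_exclusion(defn, patient, events, period):
                    continue
                raw = resolve_numerator(defn, patient, events, period)
                outcome = evaluate_measure(defn, patient, events, period)
                expected = Outcome.COMPLIANT if raw != defn.inverse else Outcome.NONCOMPLIANT
                assert outcome is expected
                checked += 1
        assert checked > 200  # the sweep actually exercised the mapping


def test_concept_registry_covers_catalog(catalog):
    """Every concept referenced by the catalog exists in the shipped registry."""
    registry = {r["concept"] for r in load_concept_registry()}
    referenced = set()
    for m in catalog:
        for c in m.conditions:
            referenced |= set(c.concepts)
        for x in m.exclusions:
            referenced |= set(x.concepts)
        for n in m.numerator:
            referenced |= set(n.concepts)
        for marker in m.required_markers:
            referenced |= set(marker)
        if m.episode:
            referenced |= set(m.episode.index_concepts)
            referenced |= set(m.episode.med_concepts)
            referenced |= set(m.episode.test_concepts)
    assert referenced <= registry
    assert referenced <= set(CONCEPT_TYPES)
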