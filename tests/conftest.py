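import dataclasses
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from fragqm import GeneratorConfig, MeasurementPeriod, load_catalog
from fragqm.records import ClinicalEvent, DocumentRecord, EventType, PatientDemographics

PERIOD = MeasurementPeriod.calendar_year(2018)


@pytest.fixture(scope="session")
def period() -> MeasurementPeriod:
    return PERIOD


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def catalog_by_id(catalog):
    return {m.measure_id: m for m in catalog}


def small_config(**overrides) -> GeneratorConfig:
    """A desk-scale generator config; defaults otherwise match the study scale."""
    base = dict(n_health_systems=2, n_ambulatory_practices=4, patients_per_org=25, seed=7)
    base.update(overrides)
    return dataclasses.replace(GeneratorConfig(), **base)


def make_patient(
    patient_id="P1",
    sex="female",
    birth_date=date(1960, 6, 15),
    originating_org="HS01",
) -> PatientDemographics:
    return PatientDemographics(
        patient_id=patient_id,
        sex=sex,
        birth_date=birth_date,
        race="white",
        ethnicity="non_hispanic",
        originating_org=originating_org,
    )


def ev(
    concept,
    event_date,
    event_type=EventType.PROCEDURE,
    value=None,
    value2=None,
    patient_id="P1",
    facility_id="HS01-F1",
) -> ClinicalEvent:
    return ClinicalEvent(
        patient_id=patient_id,
        facility_id=facility_id,
        event_type=event_type,
        concept=concept,
        event_date=event_date,
        value=value,
        value2=value2,
    )


def encounter(event_date=date(2018, 3, 1), **kw) -> ClinicalEvent:
    return ev("outpatient_encounter", event_date, EventType.ENCOUNTER, **kw)


def doc(events, received_at=None, service_date=None) -> DocumentRecord:
    events = tuple(events)
    first = events[0]
    sd = service_date or first.event_date
    return DocumentRecord(
        patient_id=first.patient_id,
        facility_id=first.facility_id,
        service_date=sd,
        received_at=received_at or datetime.combine(sd, datetime.min.time()),
        events=events,
    )


# concept -> event type used when generating random-but-typed events
CONCEPT_TYPES = {
    "outpatient_encounter": EventType.ENCOUNTER,
    "diabetes": EventType.DIAGNOSIS,
    "hypertension": EventType.DIAGNOSIS,
    "pharyngitis": EventType.DIAGNOSIS,
    "pregnancy": EventType.DIAGNOSIS,
    "esrd": EventType.DIAGNOSIS,
    "colorectal_cancer": EventType.DIAGNOSIS,
    "nephropathy": EventType.DIAGNOSIS,
    "hospice_care": EventType.FLAG,
    "hba1c": EventType.LABORATORY,
    "fobt": EventType.LABORATORY,
    "chlamydia_test": EventType.LABORATORY,
    "strep_test": EventType.LABORATORY,
    "nephropathy_screening": EventType.LABORATORY,
    "bp_reading": EventType.VITAL_SIGN,
    "bmi_percentile": EventType.VITAL_SIGN,
    "ace_arb": EventType.MEDICATION,
    "high_risk_medication": EventType.MEDICATION,
    "antibiotic": EventType.MEDICATION,
    "pneumococcal_vaccination": EventType.IMMUNIZATION,
    "mammogram": EventType.PROCEDURE,
    "colonoscopy": EventType.PROCEDURE,
    "sigmoidoscopy": EventType.PROCEDURE,
    "hysterectomy": EventType.PROCEDURE,
    "bilateral_mastectomy": EventType.PROCEDURE,
    "total_colectomy": EventType.PROCEDURE,
    "retinal_exam": EventType.PROCEDURE,
    "foot_exam": EventType.PROCEDURE,
    "fluoride_varnish": EventType.PROCEDURE,
    "cervical_cytology": EventType.PROCEDURE,
    "hpv_test": EventType.PROCEDURE,
    "sexual_activity": EventType.SCREENING,
}


def random_patient_and_events(rng: np.random.Generator, pid: str):
    """A random patient with random-but-plausibly-typed events.

    Dates span 2006–2019 so events fall inside, before and after every
    catalog window; values straddle the HbA1c and blood-pressure thresholds.
    """
    sex = "female" if rng.random() < 0.5 else "male"
    age_days = int(rng.integers(0, 96 * 365))
    patient = make_patient(
        patient_id=pid, sex=sex, birth_date=PERIOD.end - timedelta(days=age_days)
    )
    concepts = list(CONCEPT_TYPES)
    n = int(rng.integers(0, 30))
    events = []
    for _ in range(n):
        concept = concepts[int(rng.integers(0, len(concepts)))]
        d = date(2006, 1, 1) + timedelta(days=int(rng.integers(0, 14 * 365)))
        if d < patient.birth_date:
            d = patient.birth_date
        value = value2 = None
        etype = CONCEPT_TYPES[concept]
        if concept == "hba1c":
            value = float(rng.uniform(5.0, 13.0))
        elif concept == "bp_reading":
            value = float(rng.uniform(100, 180))
            value2 = float(rng.uniform(60, 110))
        elif concept == "bmi_percentile":
            value = float(rng.uniform(1, 99))
        elif etype is EventType.LABORATORY:
            value = 1.0
        events.append(
            ClinicalEvent(
                patient_id=pid,
                facility_id="HS01-F1",
                event_type=etype,
                concept=concept,
                event_date=d,
                value=value,
                value2=value2,
            )
        )
    return patient, events
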