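"""Seeded synthetic multi-facility clinical population generator.

Real HIE data underlying cross-facility quality-measurement studies are
protected and cannot be redistributed, so this module generates populations
whose *fragmentation structure* emulates such data: patients sampled
per-organization across health systems and ambulatory practices, per-patient
clinical events (encounters, diagnoses, labs, vitals, medications,
immunizations, procedures, screenings), a tunable fraction of events recorded
at non-originating facilities, and duplicate document transmissions to
exercise deduplication.

Two fragmentation-related rates are exposed:

``fragmentation_rate`` (θ)
    the marginal probability that a clinical fact is recorded at a facility
    outside the patient's originating organization; the empirical
    external-record fraction converges to θ.
``multi_facility_rate``
    the probability that a patient receives care at more than one
    organization at all.  Fragmentation in real HIE data is clustered within
    patients: with ~20 records per patient, a pure per-event coin flip at
    θ≈0.46 would make essentially every patient multi-facility, whereas only
    about four in five are.  Fragmented patients therefore route each event
    externally with probability θ/multi_facility_rate, which preserves the
    marginal θ while keeping the patient-level rate at its target.

Defaults approximate the demographic and volume marginals of a statewide-HIE
ambulatory sample: ~59.6% female overall, ~20.6 documents per patient, 46.4%
of records external, 79% of patients multi-facility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .measures import MeasurementPeriod
from .records import (
    ClinicalEvent,
    DocumentRecord,
    EventType,
    Facility,
    OrgType,
    PatientDemographics,
)

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "SyntheticPopulation", "generate_population", "emulate_study_defaults"]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# --- demographic defaults (per organization type) ----------------------------

_DEMOGRAPHICS = {
    OrgType.HEALTH_SYSTEM: {
        "female": 0.570,
        "age_bands": {(0, 4): 0.075, (5, 17): 0.094, (18, 64): 0.485, (65, 95): 0.346},
        "race": {"white": 0.849, "black": 0.043, "other": 0.108},
        "ethnicity": {"non_hispanic": 0.905, "hispanic": 0.095},
    },
    OrgType.AMBULATORY_PRACTICE: {
        "female": 0.613,
        "age_bands": {(0, 4): 0.058, (5, 17): 0.127, (18, 64): 0.573, (65, 95): 0.242},
        "race": {"white": 0.768, "black": 0.067, "other": 0.166},
        "ethnicity": {"non_hispanic": 0.928, "hispanic": 0.072},
    },
}

# condition -> (min_age, max_age, sex or None): who can plausibly carry it
_CONDITION_GATES: dict[str, tuple[int, int, str | None]] = {
    "diabetes": (18, 200, None),
    "hypertension": (18, 200, None),
    "pharyngitis": (3, 18, None),
    "pregnancy": (15, 44, "female"),
    "esrd": (18, 200, None),
    "colorectal_cancer": (50, 200, None),
    "hospice_care": (65, 200, None),
    "sexual_activity": (16, 24, "female"),
    "hysterectomy": (30, 200, "female"),
    "bilateral_mastectomy": (40, 200, "female"),
    "total_colectomy": (40, 200, None),
}

_DEFAULT_PREVALENCES: dict[str, float] = {
    "diabetes": 0.18,
    "hypertension": 0.32,
    "pharyngitis": 0.05,
    "pregnancy": 0.05,
    "esrd": 0.02,
    "colorectal_cancer": 0.01,
    "hospice_care": 0.015,
    "sexual_activity": 0.40,
    "hysterectomy": 0.15,
    "bilateral_mastectomy": 0.02,
    "total_colectomy": 0.005,
}

_DEFAULT_CARE_PROBABILITIES: dict[str, float] = {
    "hba1c_test": 0.85,
    "retinal_exam": 0.35,
    "foot_exam": 0.40,
    "nephropathy_screening": 0.45,
    "ace_arb": 0.35,
    "bp_reading_hypertensive": 0.92,
    "bp_reading_other_adult": 0.50,
    "mammogram": 0.55,
    "cervical_cytology": 0.45,
    "hpv_test": 0.25,
    "fobt": 0.10,
    "sigmoidoscopy": 0.04,
    "colonoscopy": 0.40,
    "pneumococcal_vaccination": 0.55,
    "chlamydia_test": 0.45,
    "bmi_percentile": 0.45,
    "fluoride_varnish": 0.25,
    "high_risk_medication": 0.12,
    "antibiotic_for_pharyngitis": 0.50,
    "strep_test_given_antibiotic": 0.80,
    "prior_antibiotic": 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_health_systems: int = 21
    n_ambulatory_practices: int = 32
    facilities_per_health_system: int = 3
    patients_per_org: int = 100
    period: MeasurementPeriod = field(default_factory=lambda: MeasurementPeriod.calendar_year(2018))
    fragmentation_rate: float = 0.464
    multi_facility_rate: float | None = 0.79
    lookback_years: int = 10
    mean_period_contacts: float = 14.0
    mean_historical_contacts: float = 5.0
    condition_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    care_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CARE_PROBABILITIES)
    )
    demographic_mix: Mapping = field(default_factory=lambda: _DEMOGRAPHICS)
    duplicate_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_health_systems": self.n_health_systems,
            "n_ambulatory_practices": self.n_ambulatory_practices,
            "facilities_per_health_system": self.facilities_per_health_system,
            "patients_per_org": self.patients_per_org,
            "lookback_years": self.lookback_years,
        }
        for name, v in counts.items():
            if v < 0 or (name in ("patients_per_org", "facilities_per_health_system") and v < 1):
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_health_systems + self.n_ambulatory_practices < 1:
            raise ConfigError("at least one organization is required")
        probs = {
            "fragmentation_rate": self.fragmentation_rate,
            "duplicate_rate": self.duplicate_rate,
            **{f"prevalence[{k}]": v for k, v in self.condition_prevalences.items()},
            **{f"care[{k}]": v for k, v in self.care_probabilities.items()},
        }
        if self.multi_facility_rate is not None:
            probs["multi_facility_rate"] = self.multi_facility_rate
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.multi_facility_rate is not None and self.fragmentation_rate > 0:
            if self.multi_facility_rate == 0:
                raise ConfigError("fragmentation_rate > 0 requires multi_facility_rate > 0")
            if self.fragmentation_rate > self.multi_facility_rate:
                raise ConfigError(
                    "fragmentation_rate cannot exceed multi_facility_rate "
                    f"({self.fragmentation_rate} > {self.multi_facility_rate})"
                )
        if self.fragmentation_rate > 0 and self.n_health_systems + self.n_ambulatory_practices < 2:
            raise ConfigError("fragmentation requires at least two organizations")

    @property
    def horizon_start(self) -> date:
        return self.period.start - timedelta(days=round(365.25 * self.lookback_years))


@dataclass
class SyntheticPopulation:
    patients: list[PatientDemographics]
    facilities: list[Facility]
    documents: list[DocumentRecord]

    def external_document_fraction(self) -> float:
        orgs = {f.facility_id: f.org_id for f in self.facilities}
        origin = {p.patient_id: p.originating_org for p in self.patients}
        ext = sum(1 for d in self.documents if orgs[d.facility_id] != origin[d.patient_id])
        return ext / len(self.documents) if self.documents else 0.0

    def external_event_fraction(self) -> float:
        orgs = {f.facility_id: f.org_id for f in self.facilities}
        origin = {p.patient_id: p.originating_org for p in self.patients}
        total = ext = 0
        for d in self.documents:
            n = len(d.events)
            total += n
            if orgs[d.facility_id] != origin[d.patient_id]:
                ext += n
        return ext / total if total else 0.0

    def multi_facility_fraction(self) -> float:
        orgs = {f.facility_id: f.org_id for f in self.facilities}
        origin = {p.patient_id: p.originating_org for p in self.patients}
        external_pat = {
            d.patient_id for d in self.documents if orgs[d.facility_id] != origin[d.patient_id]
        }
        return len(external_pat) / len(self.patients) if self.patients else 0.0


def emulate_study_defaults() -> GeneratorConfig:
    """Config calibrated to the study-scale marginals.

    21 health systems and 32 ambulatory practices, 100 patients sampled per
    organization, calendar-year 2018 measurement period, ≈59.6% female,
    ≈20.6 documents per patient, 46.4% of records external and 79% of
    patients seen at more than one organization.  These are approximate
    targets of the generative process, not guarantees of any single draw.
    """
    return GeneratorConfig()


# --- internal helpers ---------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights.keys())
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _random_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    """Uniform date in the closed interval [lo, hi] (hi if the interval is empty)."""
    span = (hi - lo).days
    if span <= 0:
        return hi
    return lo + timedelta(days=int(rng.integers(0, span + 1)))


def _sample_demographics(
    rng: np.random.Generator,
    mix: Mapping,
    period: MeasurementPeriod,
    patient_id: str,
    org_id: str,
) -> PatientDemographics:
    sex = "female" if rng.random() < mix["female"] else "male"
    lo, hi = _weighted_choice(rng, mix["age_bands"])
    age_days = int(rng.integers(round(lo * 365.25), round((hi + 1) * 365.25)))
    birth = period.end - timedelta(days=max(age_days, 1))
    return PatientDemographics(
        patient_id=patient_id,
        sex=sex,
        birth_date=birth,
        race=str(_weighted_choice(rng, mix["race"])),
        ethnicity=str(_weighted_choice(rng, mix["ethnicity"])),
        originating_org=org_id,
    )


@dataclass
class _RawEvent:
    event_type: EventType
    concept: str
    event_date: date
    value: float | None = None
    value2: float | None = None
    unit: str | None = None


def _patient_events(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    patient: PatientDemographics,
) -> list[_RawEvent]:
    period = cfg.period
    age = (period.end - patient.birth_date).days // 365 if patient.birth_date <= period.end else 0
    prev = cfg.condition_prevalences
    care = cfg.care_probabilities

    def has(cond: str) -> bool:
        gate = _CONDITION_GATES[cond]
        if not (gate[0] <= age <= gate[1]):
            return False
        if gate[2] is not None and patient.sex != gate[2]:
            return False
        return rng.random() < prev.get(cond, 0.0)

    conditions = {c for c in _CONDITION_GATES if has(c)}
    events: list[_RawEvent] = []

    # care-contact schedule: in-period visits plus historical visits
    n_period = max(1, int(rng.poisson(cfg.mean_period_contacts)))
    visit_dates = sorted(
        {_random_date(rng, max(period.start, patient.birth_date), period.end) for _ in range(n_period)}
    )
    hist_lo = max(cfg.horizon_start, patient.birth_date)
    if hist_lo < period.start:
        n_hist = int(rng.poisson(cfg.mean_historical_contacts))
        hist_dates = sorted(
            {
                _random_date(rng, hist_lo, period.start - timedelta(days=1))
                for _ in range(n_hist)
            }
        )
    else:
        hist_dates = []
    for d in visit_dates + hist_dates:
        events.append(_RawEvent(EventType.ENCOUNTER, "outpatient_encounter", d))

    def in_period_date() -> date:
        return visit_dates[int(rng.integers(0, len(visit_dates)))]

    def lookback_date(months: int) -> date:
        lo = max(period.end - timedelta(days=round(months * 30.44)), cfg.horizon_start, patient.birth_date)
        return _random_date(rng, lo, period.end)

    # --- condition / history events ---
    if "diabetes" in conditions:
        events.append(_RawEvent(EventType.DIAGNOSIS, "diabetes", lookback_date(24)))
    if "hypertension" in conditions:
        lo = max(period.start - timedelta(days=540), patient.birth_date, cfg.horizon_start)
        events.append(
            _RawEvent(EventType.DIAGNOSIS, "hypertension", _random_date(rng, lo, period.mid))
        )
    if "pregnancy" in conditions:
        events.append(_RawEvent(EventType.DIAGNOSIS, "pregnancy", in_period_date()))
    if "esrd" in conditions:
        events.append(_RawEvent(EventType.DIAGNOSIS, "esrd", lookback_date(60)))
    if "colorectal_cancer" in conditions:
        events.append(
            _RawEvent(EventType.DIAGNOSIS, "colorectal_cancer", lookback_date(cfg.lookback_years * 12))
        )
    if "hospice_care" in conditions:
        events.append(_RawEvent(EventType.FLAG, "hospice_care", in_period_date()))
    if "sexual_activity" in conditions:
        events.append(_RawEvent(EventType.SCREENING, "sexual_activity", in_period_date()))
    for proc in ("hysterectomy", "bilateral_mastectomy", "total_colectomy"):
        if proc in conditions:
            events.append(
                _RawEvent(EventType.PROCEDURE, proc, lookback_date(cfg.lookback_years * 12))
            )

    # --- pharyngitis episode ---
    if "pharyngitis" in conditions:
        idx = in_period_date()
        events.append(_RawEvent(EventType.DIAGNOSIS, "pharyngitis", idx))
        if rng.random() < care["antibiotic_for_pharyngitis"]:
            events.append(
                _RawEvent(
                    EventType.MEDICATION, "antibiotic", idx + timedelta(days=int(rng.integers(0, 4)))
                )
            )
            if rng.random() < care["strep_test_given_antibiotic"]:
                events.append(
                    _RawEvent(
                        EventType.LABORATORY,
                        "strep_test",
                        idx + timedelta(days=int(rng.integers(0, 3))),
                        value=1.0,
                    )
                )
            if rng.random() < care["prior_antibiotic"]:
                events.append(
                    _RawEvent(
                        EventType.MEDICATION,
                        "antibiotic",
                        idx - timedelta(days=int(rng.integers(5, 26))),
                    )
                )

    # --- preventive / disease-management services ---
    diabetic = "diabetes" in conditions
    hypertensive = "hypertension" in conditions
    if diabetic and rng.random() < care["hba1c_test"]:
        for _ in range(1 + int(rng.poisson(1.0))):
            events.append(
                _RawEvent(
                    EventType.LABORATORY,
                    "hba1c",
                    in_period_date(),
                    value=float(np.clip(rng.normal(8.2, 1.7), 4.5, 15.0)),
                    unit="%",
                )
            )
    if diabetic and rng.random() < care["retinal_exam"]:
        events.append(_RawEvent(EventType.PROCEDURE, "retinal_exam", lookback_date(24)))
    if diabetic and rng.random() < care["foot_exam"]:
        events.append(_RawEvent(EventType.PROCEDURE, "foot_exam", in_period_date()))
    if diabetic and rng.random() < care["nephropathy_screening"]:
        events.append(
            _RawEvent(EventType.LABORATORY, "nephropathy_screening", in_period_date(), value=1.0)
        )
    if (diabetic or hypertensive) and rng.random() < care["ace_arb"]:
        events.append(_RawEvent(EventType.MEDICATION, "ace_arb", in_period_date()))
    bp_p = (
        care["bp_reading_hypertensive"]
        if hypertensive
        else (care["bp_reading_other_adult"] if age >= 18 else 0.0)
    )
    if rng.random() < bp_p:
        for _ in range(1 + int(rng.poisson(1.0))):
            events.append(
                _RawEvent(
                    EventType.VITAL_SIGN,
                    "bp_reading",
                    in_period_date(),
                    value=float(np.clip(rng.normal(134, 17), 80, 220)),
                    value2=float(np.clip(rng.normal(82, 11), 40, 130)),
                    unit="mm[Hg]",
                )
            )
    if patient.sex == "female" and 50 <= age <= 74 and rng.random() < care["mammogram"]:
        events.append(_RawEvent(EventType.PROCEDURE, "mammogram", lookback_date(27)))
    if patient.sex == "female" and 21 <= age <= 64 and rng.random() < care["cervical_cytology"]:
        events.append(_RawEvent(EventType.PROCEDURE, "cervical_cytology", lookback_date(36)))
    if patient.sex == "female" and 30 <= age <= 64 and rng.random() < care["hpv_test"]:
        events.append(_RawEvent(EventType.PROCEDURE, "hpv_test", lookback_date(60)))
    if 50 <= age <= 75 and rng.random() < care["fobt"]:
        events.append(_RawEvent(EventType.LABORATORY, "fobt", in_period_date(), value=1.0))
    if 50 <= age <= 75 and rng.random() < care["sigmoidoscopy"]:
        events.append(_RawEvent(EventType.PROCEDURE, "sigmoidoscopy", lookback_date(60)))
    if 45 <= age <= 75 and rng.random() < care["colonoscopy"]:
        events.append(_RawEvent(EventType.PROCEDURE, "colonoscopy", lookback_date(120)))
    if age >= 65 and rng.random() < care["pneumococcal_vaccination"]:
        events.append(
            _RawEvent(
                EventType.IMMUNIZATION,
                "pneumococcal_vaccination",
                lookback_date(cfg.lookback_years * 12),
            )
        )
    if "sexual_activity" in conditions and rng.random() < care["chlamydia_test"]:
        events.append(_RawEvent(EventType.LABORATORY, "chlamydia_test", in_period_date(), value=1.0))
    if 3 <= age <= 17 and rng.random() < care["bmi_percentile"]:
        events.append(
            _RawEvent(
                EventType.VITAL_SIGN,
                "bmi_percentile",
                in_period_date(),
                value=float(rng.uniform(1, 99)),
                unit="%",
            )
        )
    if age <= 20 and rng.random() < care["fluoride_varnish"]:
        events.append(_RawEvent(EventType.PROCEDURE, "fluoride_varnish", in_period_date()))
    if age >= 65 and rng.random() < care["high_risk_medication"]:
        events.append(_RawEvent(EventType.MEDICATION, "high_risk_medication", in_period_date()))

    # dates never precede birth (lookback windows are clipped, but guard anyway)
    for e in events:
        if e.event_date < patient.birth_date:
            e.event_date = patient.birth_date
    return events


def generate_population(config: GeneratorConfig) -> SyntheticPopulation:
    """Generate a deterministic synthetic population from a validated config.

    Per patient: demographics are drawn from the per-organization-type mix,
    chronic conditions per prevalence, then clinical events per the care
    probabilities with dates inside the measurement period or its lookback
    horizon.  Each event is routed to the originating organization's home
    facility with probability 1−θ′ (θ′ the patient-conditional external rate),
    else to a uniformly chosen facility of another organization; events are
    bundled into per-(facility, service-date) documents with an encounter
    emitted alongside, and duplicate transmissions are injected per
    ``duplicate_rate`` with later receipt timestamps.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    period = config.period

    facilities: list[Facility] = []
    org_facilities: dict[str, list[str]] = {}
    for i in range(config.n_health_systems):
        org = f"HS{i + 1:02d}"
        org_facilities[org] = []
        for j in range(config.facilities_per_health_system):
            fid = f"{org}-F{j + 1}"
            facilities.append(Facility(fid, org, OrgType.HEALTH_SYSTEM))
            org_facilities[org].append(fid)
    for i in range(config.n_ambulatory_practices):
        org = f"AMB{i + 1:02d}"
        fid = f"{org}-F1"
        facilities.append(Facility(fid, org, OrgType.AMBULATORY_PRACTICE))
        org_facilities[org] = [fid]

    all_fids = [f.facility_id for f in facilities]
    fac_org = {f.facility_id: f.org_id for f in facilities}

    theta = config.fragmentation_rate
    mfr = config.multi_facility_rate
    patients: list[PatientDemographics] = []
    documents: list[DocumentRecord] = []
    pid_counter = 0

    org_list = [(o, OrgType.HEALTH_SYSTEM) for o in org_facilities if o.startswith("HS")] + [
        (o, OrgType.AMBULATORY_PRACTICE) for o in org_facilities if o.startswith("AMB")
    ]

    for org, org_type in org_list:
        mix = config.demographic_mix[org_type]
        external_fids = [f for f in all_fids if fac_org[f] != org]
        for _ in range(config.patients_per_org):
            pid_counter += 1
            patient = _sample_demographics(
                rng, mix, period, f"P{pid_counter:06d}", org
            )
            patients.append(patient)
            home_fid = org_facilities[org][int(rng.integers(0, len(org_facilities[org])))]

            if theta == 0:
                p_ext = 0.0
            elif mfr is None:
                p_ext = theta
            else:
                p_ext = theta / mfr if rng.random() < mfr else 0.0

            raw_events = _patient_events(rng, config, patient)
            bundles: dict[tuple[str, date], list[ClinicalEvent]] = {}
            for ev in raw_events:
                if p_ext > 0 and rng.random() < p_ext:
                    fid = external_fids[int(rng.integers(0, len(external_fids)))]
                else:
                    fid = home_fid
                bundles.setdefault((fid, ev.event_date), []).append(
                    ClinicalEvent(
                        patient_id=patient.patient_id,
                        facility_id=fid,
                        event_type=ev.event_type,
                        concept=ev.concept,
                        event_date=ev.event_date,
                        value=ev.value,
                        value2=ev.value2,
                        unit=ev.unit,
                    )
                )

            for (fid, svc_date), evs in sorted(bundles.items()):
                # a visit document always carries its encounter
                if not any(e.event_type is EventType.ENCOUNTER for e in evs):
                    evs.insert(
                        0,
                        ClinicalEvent(
                            patient_id=patient.patient_id,
                            facility_id=fid,
                            event_type=EventType.ENCOUNTER,
                            concept="outpatient_encounter",
                            event_date=svc_date,
                        ),
                    )
                received = datetime.combine(svc_date, datetime.min.time()) + timedelta(
                    seconds=int(rng.integers(0, 86400))
                )
                doc = DocumentRecord(
                    patient_id=patient.patient_id,
                    facility_id=fid,
                    service_date=svc_date,
                    received_at=received,
                    events=tuple(evs),
                )
                documents.append(doc)
                if rng.random() < config.duplicate_rate:
                    documents.append(
                        replace(
                            doc,
                            received_at=received + timedelta(hours=int(rng.integers(1, 73))),
                        )
                    )

    logger.info(
        "generated %d patients, %d facilities, %d documents",
        len(patients),
        len(facilities),
        len(documents),
    )
    return SyntheticPopulation(patients=patients, facilities=facilities, documents=documents)
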