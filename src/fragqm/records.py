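"""Clinical data model and record-level operations.

The unit of exchange is the :class:`DocumentRecord` — a dated bundle of coded
clinical events received from one facility for one patient, mirroring how a
health information exchange (HIE) receives CCD-style documents.  Facilities
belong to organizations (a health system or an ambulatory practice); the
organization at which a patient was sampled is their *originating
organization* and defines the single-EHR calculation scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OrgType",
    "EventType",
    "Scope",
    "Facility",
    "PatientDemographics",
    "ClinicalEvent",
    "DocumentRecord",
    "document_hash",
    "deduplicate_documents",
    "facility_activity_filter",
    "sample_patients",
    "scope_events",
]


class OrgType(str, Enum):
    HEALTH_SYSTEM = "health_system"
    AMBULATORY_PRACTICE = "ambulatory_practice"


class EventType(str, Enum):
    ENCOUNTER = "encounter"
    DIAGNOSIS = "diagnosis"
    LABORATORY = "laboratory"
    VITAL_SIGN = "vital_sign"
    MEDICATION = "medication"
    IMMUNIZATION = "immunization"
    PROCEDURE = "procedure"
    SCREENING = "screening"
    FLAG = "flag"


class Scope(str, Enum):
    ORIGIN_ONLY = "origin_only"
    ALL_SOURCES = "all_sources"


@dataclass(frozen=True)
class Facility:
    facility_id: str
    org_id: str
    org_type: OrgType


@dataclass(frozen=True)
class PatientDemographics:
    patient_id: str
    sex: str  # "female" | "male"
    birth_date: date
    race: str
    ethnicity: str
    originating_org: str


@dataclass(frozen=True)
class ClinicalEvent:
    """One coded clinical fact.

    ``value``/``value2`` carry numeric observations (``value2`` is used for the
    diastolic component of a blood-pressure reading); qualitative laboratory
    results carry ``value=1.0`` meaning "resulted/performed".
    """

    patient_id: str
    facility_id: str
    event_type: EventType
    concept: str
    event_date: date
    value: float | None = None
    value2: float | None = None
    unit: str | None = None

    def to_dict(self) -> dict:
        d: dict = {
            "event_type": self.event_type.value,
            "concept": self.concept,
            "event_date": self.event_date.isoformat(),
        }
        if self.value is not None:
            d["value"] = self.value
        if self.value2 is not None:
            d["value2"] = self.value2
        if self.unit is not None:
            d["unit"] = self.unit
        return d


@dataclass(frozen=True)
class DocumentRecord:
    """A per-facility, per-service-date bundle of events; the dedup unit."""

    patient_id: str
    facility_id: str
    service_date: date
    received_at: datetime
    events: tuple[ClinicalEvent, ...]

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.patient_id != self.patient_id or ev.facility_id != self.facility_id:
                raise ValueError(
                    f"event {ev.concept} does not share the document's "
                    f"patient/facility ({self.patient_id}, {self.facility_id})"
                )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "facility_id": self.facility_id,
            "service_date": self.service_date.isoformat(),
            "received_at": self.received_at.isoformat(),
            "events": [e.to_dict() for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DocumentRecord":
        pid, fid = d["patient_id"], d["facility_id"]
        events = tuple(
            ClinicalEvent(
                patient_id=pid,
                facility_id=fid,
                event_type=EventType(e["event_type"]),
                concept=e["concept"],
                event_date=date.fromisoformat(e["event_date"]),
                value=e.get("value"),
                value2=e.get("value2"),
                unit=e.get("unit"),
            )
            for e in d["events"]
        )
        return cls(
            patient_id=pid,
            facility_id=fid,
            service_date=date.fromisoformat(d["service_date"]),
            received_at=datetime.fromisoformat(d["received_at"]),
            events=events,
        )


def document_hash(doc: DocumentRecord) -> str:
    """Stable content hash of a document (used to break receipt-time ties)."""
    payload = json.dumps(doc.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def deduplicate_documents(docs: Sequence[DocumentRecord]) -> list[DocumentRecord]:
    """Keep only the most recently received document per (patient, facility, date).

    Duplicate transmissions of the same encounter document are common in HIE
    feeds; within each (patient_id, facility_id, service_date) group exactly the
    document with the maximum ``received_at`` is retained.  Nothing is merged
    across dates or facilities.  Receipt-time ties are broken by a stable
    content hash so the result is deterministic on pathological inputs.
    Output is sorted by (patient, facility, date).
    """
    best: dict[tuple[str, str, date], tuple[datetime, str, DocumentRecord]] = {}
    for doc in docs:
        key = (doc.patient_id, doc.facility_id, doc.service_date)
        cand = (doc.received_at, document_hash(doc), doc)
        prev = best.get(key)
        if prev is None or cand[:2] > prev[:2]:
            best[key] = cand
    return [best[k][2] for k in sorted(best)]


def facility_activity_filter(
    monthly_counts: Mapping[str, Sequence[int]],
    min_documents: int = 100,
    min_qualifying_months: int = 6,
) -> set[str]:
    """Facilities with >``min_qualifying_months`` months of ≥``min_documents`` docs.

    Emulates the activity screen used to drop facilities that did not
    contribute regularly during the calendar year: a facility passes iff the
    number of months with at least ``min_documents`` documents is *strictly*
    greater than ``min_qualifying_months``.
    """
    passing: set[str] = set()
    for fid, counts in monthly_counts.items():
        if len(counts) != 12:
            raise ValueError(f"facility {fid}: expected 12 monthly counts, got {len(counts)}")
        if sum(c >= min_documents for c in counts) > min_qualifying_months:
            passing.add(fid)
    return passing


def sample_patients(org_patients: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniformly sample ``n`` distinct patient ids without replacement.

    If the organization has fewer than ``n`` candidates, all are returned and a
    warning is logged.  Deterministic given ``seed``; candidates are sorted
    before sampling so the draw does not depend on input order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not org_patients:
        raise ValueError("cannot sample from an empty patient list")
    candidates = sorted(set(org_patients))
    if len(candidates) != len(org_patients):
        raise ValueError("patient ids must be distinct")
    if len(candidates) < n:
        logger.warning(
            "requested %d patients but only %d available; returning all", n, len(candidates)
        )
        return candidates
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picked)]


def scope_events(
    patient: PatientDemographics,
    docs: Iterable[DocumentRecord],
    facilities: Iterable[Facility],
    scope: Scope,
) -> list[ClinicalEvent]:
    """Resolve the events visible under a calculation scope.

    ``ORIGIN_ONLY`` keeps events from facilities whose organization is the
    patient's originating organization (the single-EHR view); ``ALL_SOURCES``
    keeps everything (the HIE view).  The origin view is a subset of the
    all-sources view by construction.
    """
    fac_org = {f.facility_id: f.org_id for f in facilities}
    out: list[ClinicalEvent] = []
    for doc in docs:
        if doc.patient_id != patient.patient_id:
            continue
        org = fac_org.get(doc.facility_id)
        if org is None:
            raise KeyError(f"unknown facility id {doc.facility_id!r}")
        if scope is Scope.ORIGIN_ONLY and org != patient.originating_org:
            continue
        out.extend(doc.events)
    return out
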