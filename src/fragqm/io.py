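"""Plain-text persistence for populations, paired results and reports.

Documents travel as newline-delimited JSON (one document per line); patients
and facilities as CSV.  The schemas are the ``to_dict`` forms of the
corresponding dataclasses and round-trip exactly.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

from .comparison import PairedResult, Report
from .measures import Outcome
from .records import DocumentRecord, Facility, OrgType, PatientDemographics
from .synth import SyntheticPopulation

__all__ = [
    "write_population",
    "read_population",
    "write_paired_results",
    "read_paired_results",
    "write_report",
]

DOCUMENTS_FILE = "documents.ndjson"
PATIENTS_FILE = "patients.csv"
FACILITIES_FILE = "facilities.csv"


def write_population(pop: SyntheticPopulation, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / DOCUMENTS_FILE, "w") as fh:
        for doc in pop.documents:
            fh.write(json.dumps(doc.to_dict(), sort_keys=True) + "\n")
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_date": p.birth_date.isoformat(),
                "race": p.race,
                "ethnicity": p.ethnicity,
                "originating_org": p.originating_org,
            }
            for p in pop.patients
        ]
    ).to_csv(out / PATIENTS_FILE, index=False)
    pd.DataFrame(
        [
            {"facility_id": f.facility_id, "org_id": f.org_id, "org_type": f.org_type.value}
            for f in pop.facilities
        ]
    ).to_csv(out / FACILITIES_FILE, index=False)


def read_population(in_dir: str | Path) -> SyntheticPopulation:
    src = Path(in_dir)
    documents = []
    with open(src / DOCUMENTS_FILE) as fh:
        for line in fh:
            if line.strip():
                documents.append(DocumentRecord.from_dict(json.loads(line)))
    pdf = pd.read_csv(src / PATIENTS_FILE, dtype=str)
    patients = [
        PatientDemographics(
            patient_id=r.patient_id,
            sex=r.sex,
            birth_date=date.fromisoformat(r.birth_date),
            race=r.race,
            ethnicity=r.ethnicity,
            originating_org=r.originating_org,
        )
        for r in pdf.itertuples()
    ]
    fdf = pd.read_csv(src / FACILITIES_FILE, dtype=str)
    facilities = [
        Facility(r.facility_id, r.org_id, OrgType(r.org_type)) for r in fdf.itertuples()
    ]
    return SyntheticPopulation(patients=patients, facilities=facilities, documents=documents)


def write_paired_results(paired: Sequence[PairedResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "measure_id": r.measure_id,
                "origin_outcome": r.origin_outcome.value,
                "all_outcome": r.all_outcome.value,
                "category": r.category.value,
            }
            for r in paired
        ]
    ).to_csv(path, index=False)


def read_paired_results(path: str | Path) -> list[PairedResult]:
    df = pd.read_csv(path, dtype=str)
    return [
        PairedResult(
            patient_id=r.patient_id,
            measure_id=r.measure_id,
            origin_outcome=Outcome(r.origin_outcome),
            all_outcome=Outcome(r.all_outcome),
        )
        for r in df.itertuples()
    ]


def write_report(report: Report, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
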