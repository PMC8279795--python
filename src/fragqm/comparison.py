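"""Dual-scope measure calculation, discrepancy classification and aggregation.

Every (patient, measure) pair is evaluated twice: once on the data recorded
by the patient's originating organization (the single-EHR view) and once on
all sources (the HIE view, taken as the reference standard because it is the
more complete record).  A calculation is *applicable* when its all-sources
outcome is not NOT_APPLICABLE; eligibility logic is existential, so adding
data can never make an applicable calculation inapplicable.  Discrepancies
between the two outcomes are classified into the four named transitions
plus a pooled OTHER bucket for anything involving exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .measures import MeasureDefinition, MeasurementPeriod, Outcome, evaluate_measure
from .records import PatientDemographics, Scope, scope_events
from .stats import SymmetryTestResult, asymptotic_symmetry_test, bh_fdr, monte_carlo_symmetry_test
from .synth import SyntheticPopulation

__all__ = [
    "OUTCOME_ORDER",
    "DiscrepancyCategory",
    "PairedResult",
    "ComplianceChange",
    "MeasureSummary",
    "Report",
    "paired_evaluate",
    "classify_transition",
    "performance_rate",
    "compliance_change",
    "transition_table",
    "aggregate_report",
]

# fixed index order for 4x4 transition tables
OUTCOME_ORDER: tuple[Outcome, ...] = (
    Outcome.NOT_APPLICABLE,
    Outcome.EXCLUDED,
    Outcome.NONCOMPLIANT,
    Outcome.COMPLIANT,
)
_IDX = {o: i for i, o in enumerate(OUTCOME_ORDER)}


class DiscrepancyCategory(str, Enum):
    NA_TO_NC = "NA_TO_NC"
    NA_TO_CC = "NA_TO_CC"
    NC_TO_CC = "NC_TO_CC"
    CC_TO_NC = "CC_TO_NC"
    OTHER = "OTHER"
    NONE = "NONE"


_NAMED = {
    (Outcome.NOT_APPLICABLE, Outcome.NONCOMPLIANT): DiscrepancyCategory.NA_TO_NC,
    (Outcome.NOT_APPLICABLE, Outcome.COMPLIANT): DiscrepancyCategory.NA_TO_CC,
    (Outcome.NONCOMPLIANT, Outcome.COMPLIANT): DiscrepancyCategory.NC_TO_CC,
    (Outcome.COMPLIANT, Outcome.NONCOMPLIANT): DiscrepancyCategory.CC_TO_NC,
}


@dataclass(frozen=True)
class PairedResult:
    patient_id: str
    measure_id: str
    origin_outcome: Outcome
    all_outcome: Outcome

    @property
    def applicable(self) -> bool:
        return self.all_outcome is not Outcome.NOT_APPLICABLE

    @property
    def category(self) -> DiscrepancyCategory:
        return classify_transition(self.origin_outcome, self.all_outcome)


def classify_transition(origin: Outcome, all_sources: Outcome) -> DiscrepancyCategory:
    """Classify an outcome transition between the two calculation scopes."""
    if origin is all_sources:
        return DiscrepancyCategory.NONE
    return _NAMED.get((origin, all_sources), DiscrepancyCategory.OTHER)


def paired_evaluate(
    population: SyntheticPopulation,
    catalog: Sequence[MeasureDefinition],
    period: MeasurementPeriod,
) -> list[PairedResult]:
    """Evaluate every measure for every patient under both scopes.

    Documents must already be deduplicated.  Returns one result per
    patient × measure (|patients| · |catalog| results).
    """
    docs_by_patient: dict[str, list] = {}
    for doc in population.documents:
        docs_by_patient.setdefault(doc.patient_id, []).append(doc)
    results: list[PairedResult] = []
    for patient in population.patients:
        docs = docs_by_patient.get(patient.patient_id, [])
        origin_events = scope_events(patient, docs, population.facilities, Scope.ORIGIN_ONLY)
        all_events = scope_events(patient, docs, population.facilities, Scope.ALL_SOURCES)
        for defn in catalog:
            results.append(
                PairedResult(
                    patient_id=patient.patient_id,
                    measure_id=defn.measure_id,
                    origin_outcome=evaluate_measure(defn, patient, origin_events, period),
                    all_outcome=evaluate_measure(defn, patient, all_events, period),
                )
            )
    return results


def performance_rate(outcomes: Iterable[Outcome]) -> float | None:
    """COMPLIANT / (COMPLIANT + NONCOMPLIANT); ``None`` when undefined.

    EXCLUDED and NOT_APPLICABLE outcomes are omitted from the denominator, as
    in standard quality reporting.
    """
    cc = nc = 0
    for o in outcomes:
        if o is Outcome.COMPLIANT:
            cc += 1
        elif o is Outcome.NONCOMPLIANT:
            nc += 1
    if cc + nc == 0:
        return None
    return cc / (cc + nc)


@dataclass(frozen=True)
class ComplianceChange:
    """Net percentage-point change in performance rate between scopes."""

    change_pp: float | None
    origin_rate: float | None
    all_rate: float | None
    reason: str | None = None


def compliance_change(paired: Sequence[PairedResult], measure_id: str) -> ComplianceChange:
    """100 × (all-sources rate − origin rate) for one measure.

    The origin rate is computed over origin-applicable outcomes only (what a
    single-EHR submission would report); the all-sources rate over
    all-applicable outcomes.  Balanced opposite flips (equal NC→CC and CC→NC
    counts on a balanced panel) therefore net to zero even though each flip
    counts as a discrepancy.
    """
    sub = [r for r in paired if r.measure_id == measure_id]
    origin = performance_rate(r.origin_outcome for r in sub)
    allr = performance_rate(r.all_outcome for r in sub)
    if allr is None:
        return ComplianceChange(None, origin, None, reason="no applicable all-sources outcomes")
    if origin is None:
        return ComplianceChange(None, None, allr, reason="origin-scope rate undefined")
    return ComplianceChange(100.0 * (allr - origin), origin, allr)


def transition_table(
    paired: Sequence[PairedResult], measure_id: str | None = None
) -> np.ndarray:
    """4×4 origin×all outcome counts, indexed by ``OUTCOME_ORDER``."""
    table = np.zeros((4, 4), dtype=int)
    for r in paired:
        if measure_id is not None and r.measure_id != measure_id:
            continue
        table[_IDX[r.origin_outcome], _IDX[r.all_outcome]] += 1
    return table


@dataclass
class MeasureSummary:
    measure_id: str
    description: str
    applicable_count: int
    category_counts: dict[str, int]
    origin_rate: float | None
    all_rate: float | None
    compliance_change_pp: float | None
    change_reason: str | None
    p_value: float | None = None
    q_value: float | None = None
    statistic: float | None = None
    test_method: str | None = None

    @property
    def discrepancy_count(self) -> int:
        return sum(v for k, v in self.category_counts.items() if k != "NONE")

    def to_dict(self) -> dict:
        return {
            "measure_id": self.measure_id,
            "description": self.description,
            "applicable_calculations": self.applicable_count,
            **{k.lower(): v for k, v in self.category_counts.items()},
            "discrepancies": self.discrepancy_count,
            "origin_rate": self.origin_rate,
            "all_sources_rate": self.all_rate,
            "compliance_change_pp": self.compliance_change_pp,
            "change_reason": self.change_reason,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "test_method": self.test_method,
        }


@dataclass
class OrgSummary:
    org_id: str
    org_type: str
    applicable_count: int
    changed_count: int

    @property
    def change_rate(self) -> float | None:
        return self.changed_count / self.applicable_count if self.applicable_count else None

    def to_dict(self) -> dict:
        return {
            "org_id": self.org_id,
            "org_type": self.org_type,
            "applicable_calculations": self.applicable_count,
            "changed": self.changed_count,
            "change_rate": self.change_rate,
        }


@dataclass
class Report:
    n_patients: int
    applicable_calculations: int
    discrepancies: int
    patients_with_applicable: int
    patients_with_change: int
    category_totals: dict[str, int]
    measures: list[MeasureSummary]
    organizations: list[OrgSummary]
    overall_test: SymmetryTestResult
    per_patient_change: dict[str, bool] = field(default_factory=dict)

    @property
    def overall_change_fraction(self) -> float | None:
        if self.applicable_calculations == 0:
            return None
        return self.discrepancies / self.applicable_calculations

    @property
    def patient_change_fraction(self) -> float | None:
        if self.n_patients == 0:
            return None
        return self.patients_with_change / self.n_patients

    def to_dict(self) -> dict:
        t = self.overall_test
        return {
            "n_patients": self.n_patients,
            "applicable_calculations": self.applicable_calculations,
            "discrepancies": self.discrepancies,
            "overall_change_fraction": self.overall_change_fraction,
            "patients_with_applicable": self.patients_with_applicable,
            "patients_with_change": self.patients_with_change,
            "patient_change_fraction": self.patient_change_fraction,
            "category_totals": dict(self.category_totals),
            "overall_test": {
                "statistic": t.statistic,
                "dof": t.dof,
                "p_value": t.p_value,
                "method": t.method.value,
            },
            "measures": [m.to_dict() for m in self.measures],
            "organizations": [o.to_dict() for o in self.organizations],
        }


def aggregate_report(
    paired: Sequence[PairedResult],
    population: SyntheticPopulation,
    catalog: Sequence[MeasureDefinition],
    n_resamples: int = 2000,
    seed: int | None = None,
) -> Report:
    """Aggregate paired results into per-measure, per-organization and overall
    summaries with symmetry tests.

    Per-measure significance uses the Monte Carlo symmetry test (the
    per-measure tables are sparse) with Benjamini–Hochberg FDR adjustment
    across measures; the pooled table is tested asymptotically.
    """
    applicable = [r for r in paired if r.applicable]
    cat_totals = {c.value: 0 for c in DiscrepancyCategory}
    for r in applicable:
        cat_totals[r.category.value] += 1
    discrepancies = sum(v for k, v in cat_totals.items() if k != "NONE")

    desc = {m.measure_id: m.description for m in catalog}
    summaries: list[MeasureSummary] = []
    rng_seeds = np.random.SeedSequence(seed).spawn(len(catalog))
    for defn, ss in zip(catalog, rng_seeds):
        mid = defn.measure_id
        sub = [r for r in applicable if r.measure_id == mid]
        counts = {c.value: 0 for c in DiscrepancyCategory}
        for r in sub:
            counts[r.category.value] += 1
        cc = compliance_change(paired, mid)
        test = monte_carlo_symmetry_test(
            transition_table([r for r in paired if r.measure_id == mid]),
            n_resamples=n_resamples,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        summaries.append(
            MeasureSummary(
                measure_id=mid,
                description=desc.get(mid, mid),
                applicable_count=len(sub),
                category_counts=counts,
                origin_rate=cc.origin_rate,
                all_rate=cc.all_rate,
                compliance_change_pp=cc.change_pp,
                change_reason=cc.reason,
                p_value=test.p_value,
                statistic=test.statistic,
                test_method=test.method.value,
            )
        )
    qs = bh_fdr([s.p_value for s in summaries])
    for s, q in zip(summaries, qs):
        s.q_value = q

    origin_org = {p.patient_id: p.originating_org for p in population.patients}
    org_types = {f.org_id: f.org_type.value for f in population.facilities}
    per_org: dict[str, OrgSummary] = {}
    for r in applicable:
        org = origin_org[r.patient_id]
        summ = per_org.setdefault(org, OrgSummary(org, org_types.get(org, "unknown"), 0, 0))
        summ.applicable_count += 1
        if r.category is not DiscrepancyCategory.NONE:
            summ.changed_count += 1

    per_patient_change: dict[str, bool] = {}
    patients_with_applicable: set[str] = set()
    for r in applicable:
        patients_with_applicable.add(r.patient_id)
        if r.category is not DiscrepancyCategory.NONE:
            per_patient_change[r.patient_id] = True
        else:
            per_patient_change.setdefault(r.patient_id, False)

    overall = asymptotic_symmetry_test(transition_table(list(paired)))
    return Report(
        n_patients=len(population.patients),
        applicable_calculations=len(applicable),
        discrepancies=discrepancies,
        patients_with_applicable=len(patients_with_applicable),
        patients_with_change=sum(per_patient_change.values()),
        category_totals=cat_totals,
        measures=summaries,
        organizations=[per_org[k] for k in sorted(per_org)],
        overall_test=overall,
        per_patient_change=per_patient_change,
    )
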