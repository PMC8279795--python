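# Methods

## Problem and model

`fragqm` models the measurement error introduced when ambulatory electronic
clinical quality measures (eCQMs) are computed from one organization's EHR
while the patient's record is fragmented across organizations.  The unit of
analysis is the (patient, measure) *calculation*, evaluated under two data
scopes — originating organization only, and all sources — to one of four
outcomes: NOT_APPLICABLE (denominator not met), EXCLUDED, NONCOMPLIANT or
COMPLIANT.  The all-sources calculation is treated as the reference standard
because it uses strictly more information; "applicable" calculations are
those applicable under that reference scope, so transitions out of
NOT_APPLICABLE count as discrepancies.  Origin-scope performance rates are
computed over origin-applicable outcomes only, since that is what a
single-EHR submission would report; this choice is a documented convention,
not an identity, and flipping it changes only the rate denominators, not the
discrepancy counts.

Eligibility logic is deliberately *existential* (presence of a diagnosis,
encounter or marker, never absence), which yields the central monotonicity
property: adding data can move a calculation out of NOT_APPLICABLE but never
into it.  All classification and aggregation downstream relies on this.

## Measure emulations

The 14 measure definitions in `fragqm/data/measure_catalog.yaml` are
concept-level emulations, not certified implementations: official value sets
(VSAC) and CQL logic are licensed artifacts and are out of scope.  Each
emulation preserves the structural drivers of cross-scope discrepancy — the
age/sex gates, denominator diagnoses with recency windows (diabetes within
24 months of period end; hypertension on/before mid-period), qualifying
encounter requirements, ever- vs in-period exclusions, numerator lookback
windows (27 months for mammography, 3/5 years for cervical cytology/HPV,
5/10 years for sigmoidoscopy/colonoscopy), most-recent-observation value
thresholds (HbA1c > 9%, BP < 140/90), inverse measures whose raw numerator
is undesirable (HbA1c poor control, high-risk medication use), and one
episodic measure (pharyngitis testing).  Windows are closed intervals; ages
are completed years at period end; a Feb-29 birthday completes its year on
Feb-28 in non-leap years; same-date observation ties are broken by a stable
(date, concept, value) ordering.

Two points where the four-state mapping required a decision:

* HbA1c control: a diabetic with *no* in-period HbA1c result is counted as
  poor control (raw numerator met for the inverse measure); BP control with
  no in-period reading is counted as not controlled.  Both follow the usual
  "absence of evidence is failure of control" convention of these measures.
* Pharyngitis episodes: no qualifying episode (in-period pharyngitis
  diagnosis + antibiotic within 3 days) → NOT_APPLICABLE; episodes exist but
  every one has an antibiotic in the prior 30 days → EXCLUDED; otherwise
  COMPLIANT iff every remaining episode has a strep test within ±3 days.

## Synthetic data generator

The generator emulates the fragmentation structure of a statewide HIE feed.
Organizations are 21 health systems (3 facilities each) and 32 ambulatory
practices (1 facility), 100 patients per organization by default.
Demographics are drawn per organization type (health systems: 57.0% female,
age bands 7.5/9.4/48.5/34.6% for 0–4/5–17/18–64/65+; ambulatory practices:
61.3% female, 5.8/12.7/57.3/24.2%), giving ≈59.6% female overall.  Chronic
conditions are assigned independently per patient with age/sex gates
(diabetes 18% of adults, hypertension 32%, pharyngitis 5% of 3–18-year-olds,
etc.); comorbidity correlation is not modelled because the discrepancy
mechanism does not need it.  Care events are then drawn per service from
per-eligible-patient probabilities (e.g. mammography 0.55 within 27 months,
colonoscopy 0.40 within 10 years, HbA1c testing 0.85 with values
N(8.2, 1.7²)%, BP readings N(134, 17²)/N(82, 11²) mm Hg).  These service
probabilities and prevalences are field-realistic defaults chosen once to
give roughly the published mix of applicable calculations (≈2.4 applicable
measures per patient, pharyngitis episodes rare); they are exposed in
`GeneratorConfig` rather than asserted as fidelity claims.

Care contacts are ~Poisson(14) in-period visit dates plus ~Poisson(5)
historical dates within a 10-year lookback horizon (the longest numerator
window, colonoscopy, needs 10 years); in-period services land on visit
dates, lookback services on their own dates.  Events bundle into one
document per (facility, service date), each carrying an encounter, giving
≈20.6 documents per patient after deduplication.

**Fragmentation.**  `fragmentation_rate` θ (default 0.464) is the marginal
probability that an event is recorded outside the originating organization.
Real fragmentation is clustered within patients: with ~20 documents each, an
independent per-event coin at θ=0.464 would make essentially every patient
multi-facility, whereas about 79% are.  The generator therefore draws a
patient-level "fragmented" indicator with probability `multi_facility_rate`
(default 0.79) and routes fragmented patients' events externally with
probability θ/0.79, to a uniformly chosen facility of another organization.
This preserves both marginals (external-event fraction → θ; multi-facility
fraction → 0.79) and the spec θ semantics (θ=0 ⇒ no external events).
Setting `multi_facility_rate: null` recovers pure per-event routing, which
the parameter-recovery test uses.  Encounters emitted alongside externally
routed events add a small (<1 point) upward bias to the realized
external-event fraction; this sits well inside the Monte Carlo tolerance the
calibration test uses.  Referral structure (which external organization is
chosen) is uniform; real referral networks are not modelled.

Duplicate documents are re-emitted with probability `duplicate_rate`
(default 0.05) with a later receipt timestamp; deduplication keeps the most
recently received document per (patient, facility, service date), breaking
receipt ties by content hash so pathological inputs stay deterministic.  The
facility activity filter ("more than 6 months with ≥100 documents") reads
"more than" strictly: ≥7 qualifying months, with both thresholds
configurable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: terminology noise (it emits clean concept labels,
not real codes), free-text or missing structured fields, patient-identity
mismatches across facilities, referral network structure, organization-level
heterogeneity in recording quality (the published 100%-discrepancy practices
with malformed encounters), and correlated comorbidity.  Results on this
generator demonstrate the *mechanism* and validate the pipeline's logic;
they are not estimates of any real system's discrepancy rates.

## Statistics

The overall test is a Bowker-type symmetry statistic on the pooled 4×4
transition table, Σ_{i<j}(n_ij−n_ji)²/(n_ij+n_ji) over pairs with discordant
mass, referred to χ² with one dof per contributing pair (this reduces to
McNemar's test for two categories; a table with no discordant mass is
defined to have p = 1).  Per-measure tables are sparse, so each measure uses
a Monte Carlo test: under the null each discordant unit's direction is a
fair coin within its unordered pair, so each pair's count is resampled as
Binomial(n_ij+n_ji, ½); p = (1 + #{T* ≥ T})/(1 + B) with B = 2000 resamples
by default — the add-one correction avoids p = 0 and keeps the test
level-valid.  The 14 per-measure p-values are adjusted with
Benjamini–Hochberg FDR (delegated to statsmodels).  No construction for the
"multinomial extension" is canonical, so both asymptotic and Monte Carlo
variants are exposed; patients contribute up to 14 calculations each and
within-patient correlation across measures is not modelled — per-measure
tests are unaffected, but the pooled test should be read descriptively.

Statistic floating-point comparisons in the Monte Carlo tail count use a
1e-12 tolerance so exact ties are not lost to rounding.  Performance rates
with an empty CC+NC denominator are reported as undefined (rendered as
dashes), never as zero.

## Problem sizes and numerical choices

The shipped test and acceptance runs use reduced populations (6–10
organizations × 25–60 patients, ~50k events for calibration checks) — ample
for the binomial concentration the assertions rely on, and chosen as the
package's standard desk-scale configurations.  Monte Carlo checks use
20 000 resamples against exact 2^d enumeration (d ≤ 12) and 1 000
simulations for type-I calibration at α = 0.05.  Determinism: every random
draw flows from `numpy.random.default_rng` seeded from the config; identical
configs produce byte-identical populations and reports.

## Known limitations

* Measure logic is an emulation; per-measure discrepancy magnitudes depend
  on generator parameters and are not reproduction targets of any published
  table.
* Exclusion-involving transitions are pooled into a single OTHER category.
* The pooled symmetry test ignores within-patient correlation.
* The generator's external-facility choice is uniform; per-organization
  discrepancy-rate variance is therefore narrower than in real networks.
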