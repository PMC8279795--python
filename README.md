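# fragqm — quality measurement under care fragmentation

Ambulatory electronic clinical quality measures (eCQMs) are normally computed
from a single organization's EHR, yet most patients receive care at more than
one organization per year.  When a diagnosis, lab result, vaccination or
procedure is recorded only at an outside facility, the home organization's
measure calculation is wrong in a specific, classifiable way: a patient may
look ineligible (missing denominator diagnosis or encounter), spuriously
noncompliant (missing numerator evidence), or spuriously compliant (a newer
out-of-network observation overrides the local one).  These errors feed
directly into value-based payment (e.g. MIPS) and patient safety.

`fragqm` quantifies this effect end to end.  Because the multi-source
clinical feeds held by health information exchanges (HIEs) are protected, the
package ships a seeded synthetic generator whose fragmentation structure
emulates such a feed, and computes every quality measure twice per patient:

1. **origin-only scope** — data recorded by the patient's originating
   organization (what a single EHR would submit);
2. **all-sources scope** — data from every facility (the reference standard).

Each (patient, measure) pair yields one of four outcomes — `NOT_APPLICABLE`,
`EXCLUDED`, `NONCOMPLIANT`, `COMPLIANT` — and the paired outcomes are
classified into the transitions NA→NC, NA→CC, NC→CC, CC→NC, plus a pooled
"other" bucket for exclusion-involving changes.  The per-measure performance
rate is `CC / (CC + NC)` and the *compliance change* is the percentage-point
difference between the two scopes' rates.

## The statistical layer

Paired origin × all-sources outcomes form a 4×4 transition table.  Under the
null hypothesis that data aggregation shifts outcomes in no preferred
direction, the table is symmetric, which is tested with a Bowker-type
statistic (a multinomial extension of McNemar's test):

    T = Σ_{i<j} (n_ij − n_ji)² / (n_ij + n_ji),   over pairs with n_ij + n_ji > 0

with one χ² degree of freedom per contributing pair.  Because per-measure
tables are sparse, each measure is tested with a Monte Carlo variant (each
discordant unit's direction resampled as a fair coin, p-value with add-one
correction) and the 14 p-values are adjusted with Benjamini–Hochberg FDR.

## Worked example

A reduced-scale run (10 organizations × 50 patients, default fragmentation
46.4% of records external):

```sh
cat > example.yaml <<'EOF'
generator:
  n_health_systems: 4
  n_ambulatory_practices: 6
  patients_per_org: 50
  seed: 3
n_resamples: 2000
stats_seed: 3
EOF
fragqm run-all --config example.yaml --out-dir example_run
```

prints

```
1227 applicable calculations; 405 changed (33.0%); 224 patients affected (44.8%)
```

meaning: of 500 patients, 1227 (patient, measure) calculations were
applicable under the all-sources reference scope (~2.5 per patient); 405 of
them (33.0%) gave a different outcome when restricted to origin-only data;
and 224 patients had at least one measure change.  The rendered per-measure
table (`example_run/measure_table.txt`) begins:

```
                                               measure compliance_change_pct  applicable_calculations  na_to_nc  na_to_cc  nc_to_cc  cc_to_nc  other   q_value
                Chlamydia screening for women (cms153)                 -23.6                       11         5         1         0         0      0   0.07521
 Use of high-risk medications in older adults (cms156)                  -2.4                      123         0         1         0         3      0    0.2669
                    Diabetes: annual eye exam (cms131)                  +9.7                       74        23        10         6         0      0 0.0007774
...
```

Reading the high-risk-medication row: adding external data revealed
medication orders the originating organization never saw, so compliance
*fell* by 2.4 points — the one measure where aggregation hurts reported
performance, exactly because its raw numerator (a high-risk order in an
elderly patient) is undesirable.  The diagnosis-gated diabetes measures show
large NA→* columns: the denominator diagnosis lived only at an external
facility.  Re-running the same config reproduces the report byte for byte;
`fragqm simulate | ingest | compare | report` expose the stages separately,
with every intermediate artifact (NDJSON documents, patients/facilities CSVs,
paired-results CSV, report JSON) persisted for audit.

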