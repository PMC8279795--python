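# Simplified emulations of 14 MIPS-eligible ambulatory eCQMs.
#
# These preserve each measure's structure (age/sex gates, denominator
# diagnoses, qualifying encounters, exclusions, numerator lookback windows,
# value thresholds, inverse logic) at concept level; they do not use official
# value sets or CQL and are not certified measure implementations.
# Windows are closed intervals; ages are completed years at the end of the
# measurement period. Every window and threshold here is overridable by
# pointing the pipeline at an edited copy of this file.

measures:
  - id: cms122
    description: "Diabetes: hemoglobin A1c poor control (>9%)"
    inverse: true
    age: {min: 18, max: 75}
    conditions:
      - {concepts: [diabetes], lookback_months: 24}
    requires_encounter: true
    exclusions:
      - {concepts: [hospice_care], window: {kind: period}}
    numerator:
      # raw numerator = poor control: most recent in-period HbA1c above 9%,
      # or no HbA1c result at all
      - concepts: [hba1c]
        window: {kind: period}
        value_test: hba1c_gt_9
        met_if_absent: true

  - id: cms131
    description: "Diabetes: annual eye exam"
    age: {min: 18, max: 75}
    conditions:
      - {concepts: [diabetes], lookback_months: 24}
    requires_encounter: true
    exclusions:
      - {concepts: [hospice_care], window: {kind: period}}
    numerator:
      - {concepts: [retinal_exam], window: {kind: period_plus_months, months: 12}}

  - id: cms123
    description: "Diabetes: annual foot exam"
    age: {min: 18, max: 75}
    conditions:
      - {concepts: [diabetes], lookback_months: 24}
    requires_encounter: true
    exclusions:
      - {concepts: [hospice_care], window: {kind: period}}
    numerator:
      - {concepts: [foot_exam], window: {kind: period}}

  - id: cms134
    description: "Diabetes: medical attention for nephropathy"
    age: {min: 18, max: 75}
    conditions:
      - {concepts: [diabetes], lookback_months: 24}
    requires_encounter: true
    exclusions:
      - {concepts: [hospice_care], window: {kind: period}}
    numerator:
      - {concepts: [nephropathy_screening], window: {kind: period}}
      - {concepts: [ace_arb], window: {kind: period}}
      - {concepts: [nephropathy], window: {kind: period}}

  - id: cms165
    description: "Controlling high blood pressure"
    age: {min: 18, max: 85}
    conditions:
      - {concepts: [hypertension], anchor: period_mid}
    requires_encounter: true
    exclusions:
      - {concepts: [esrd], window: {kind: ever}}
      - {concepts: [pregnancy], window: {kind: period}}
    numerator:
      # most recent in-period reading <140 systolic and <90 diastolic;
      # no in-period reading counts as not controlled
      - concepts: [bp_reading]
        window: {kind: period}
        value_test: bp_controlled

  - id: cms125
    description: "Breast cancer screening"
    sex: female
    age: {min: 51, max: 74}
    requires_encounter: true
    exclusions:
      - {concepts: [bilateral_mastectomy], window: {kind: ever}}
    numerator:
      - {concepts: [mammogram], window: {kind: before_end_months, months: 27}}

  - id: cms124
    description: "Cervical cancer screening"
    sex: female
    age: {min: 23, max: 64}
    requires_encounter: true
    exclusions:
      - {concepts: [hysterectomy], window: {kind: ever}}
    numerator:
      - {concepts: [cervical_cytology], window: {kind: before_end_months, months: 36}}
      - {concepts: [hpv_test], window: {kind: before_end_months, months: 60}, min_age: 30}

  - id: cms130
    description: "Colorectal cancer screening"
    age: {min: 50, max: 75}
    requires_encounter: true
    exclusions:
      - {concepts: [total_colectomy], window: {kind: ever}}
      - {concepts: [colorectal_cancer], window: {kind: ever}}
    numerator:
      - {concepts: [fobt], window: {kind: period}}
      - {concepts: [sigmoidoscopy], window: {kind: before_end_months, months: 60}}
      - {concepts: [colonoscopy], window: {kind: before_end_months, months: 120}}

  - id: cms127
    description: "Pneumococcal vaccination status for older adults"
    age: {min: 65}
    requires_encounter: true
    numerator:
      - {concepts: [pneumococcal_vaccination], window: {kind: ever}}

  - id: cms153
    description: "Chlamydia screening for women"
    sex: female
    age: {min: 16, max: 24}
    requires_encounter: true
    required_markers:
      - [sexual_activity]
    numerator:
      - {concepts: [chlamydia_test], window: {kind: period}}

  - id: cms155
    description: "Pediatric weight assessment: BMI percentile documented"
    age: {min: 3, max: 17}
    requires_encounter: true
    exclusions:
      - {concepts: [pregnancy], window: {kind: period}}
    numerator:
      - {concepts: [bmi_percentile], window: {kind: period}}

  - id: cms146
    description: "Appropriate testing for children with pharyngitis"
    age: {min: 3, max: 18}
    episodic: true
    episode:
      index_concepts: [pharyngitis]
      med_concepts: [antibiotic]
      med_within_days: 3
      prior_med_exclusion_days: 30
      test_concepts: [strep_test]
      test_within_days: 3

  - id: cms156
    description: "Use of high-risk medications in older adults"
    inverse: true
    age: {min: 65}
    requires_encounter: true
    exclusions:
      - {concepts: [hospice_care], window: {kind: period}}
    numerator:
      - {concepts: [high_risk_medication], window: {kind: period}}

  - id: cms74
    description: "Primary caries prevention: fluoride varnish application"
    age: {min: 0, max: 20}
    requires_encounter: true
    numerator:
      - {concepts: [fluoride_varnish], window: {kind: period}}
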