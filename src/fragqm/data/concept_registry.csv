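concept,event_type,illustrative_code,code_system,description
outpatient_encounter,encounter,99213,CPT,Office or other outpatient visit
diabetes,diagnosis,E11.9,ICD-10-CM,Type 2 diabetes mellitus without complications
hypertension,diagnosis,I10,ICD-10-CM,Essential (primary) hypertension
pharyngitis,diagnosis,J02.9,ICD-10-CM,Acute pharyngitis
pregnancy,diagnosis,Z33.1,ICD-10-CM,Pregnant state incidental
esrd,diagnosis,N18.6,ICD-10-CM,End stage renal disease
colorectal_cancer,diagnosis,C18.9,ICD-10-CM,Malignant neoplasm of colon
nephropathy,diagnosis,N08,ICD-10-CM,Glomerular disorders / diabetic nephropathy
hospice_care,flag,Z51.5,ICD-10-CM,Encounter for palliative/hospice care
hba1c,laboratory,4548-4,LOINC,Hemoglobin A1c/Hemoglobin.total in blood
fobt,laboratory,2335-8,LOINC,Hemoglobin.gastrointestinal in stool (FOBT)
chlamydia_test,laboratory,43304-5,LOINC,Chlamydia trachomatis rRNA
strep_test,laboratory,11268-0,LOINC,Streptococcus pyogenes antigen rapid test
nephropathy_screening,laboratory,14959-1,LOINC,Microalbumin/creatinine ratio in urine
bp_reading,vital_sign,85354-9,LOINC,Blood pressure panel systolic and diastolic
bmi_percentile,vital_sign,59576-9,LOINC,Body mass index percentile per age and sex
ace_arb,medication,314076,RxNorm,Lisinopril 10 mg oral tablet (ACE inhibitor)
high_risk_medication,medication,197589,RxNorm,Diazepam 10 mg oral tablet (Beers-list example)
antibiotic,medication,308182,RxNorm,Amoxicillin 250 mg oral capsule
pneumococcal_vaccination,immunization,33,CVX,Pneumococcal polysaccharide vaccine PPSV23
mammogram,procedure,77067,CPT,Screening mammography bilateral
colonoscopy,procedure,45378,CPT,Colonoscopy flexible diagnostic
sigmoidoscopy,procedure,45330,CPT,Sigmoidoscopy flexible diagnostic
hysterectomy,procedure,58150,CPT,Total abdominal hysterectomy
bilateral_mastectomy,procedure,19303,CPT,Mastectomy simple complete (bilateral)
total_colectomy,procedure,44150,CPT,Colectomy total abdominal
retinal_exam,procedure,92227,CPT,Remote retinal imaging for disease detection
foot_exam,procedure,G0247,HCPCS,Routine foot care with diabetic sensory exam
fluoride_varnish,procedure,99188,CPT,Application of topical fluoride varnish
cervical_cytology,procedure,88142,CPT,Cytopathology cervical or vaginal
hpv_test,procedure,87624,CPT,HPV high-risk types detection
sexual_activity,screening,64004-4,LOINC,Sexual activity history marker
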