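{
  "description": "Default cohort CSV schema: canonical column names and categorical spellings. 'columns' maps package field name -> CSV column name; 'values' maps field name -> {source spelling -> canonical value}. Both default to identity; override with --schema to remap foreign CSVs.",
  "columns": {},
  "values": {},
  "canonical_columns": [
    "patient_id", "age", "sex", "residence", "mobility", "mental_status",
    "cognitive_impairment", "asa_grade", "hemoglobin", "serum_urea", "cci",
    "n_comorbidities", "fracture_type", "in_hospital_fracture",
    "nursing_care_certification", "copd", "pneumonia",
    "ischemic_heart_disease", "prior_mi", "arrhythmia", "chf", "malnutrition",
    "electrolyte_disorder", "renal_disease", "liver_disease_moderate_severe",
    "deficiency_anemia", "chronic_pulmonary_disease", "malignancy",
    "dxa_t_score", "treated_surgically", "admission_date", "dead_1y",
    "followup_months", "lost_to_followup", "periprosthetic"
  ],
  "enums": {
    "sex": ["male", "female"],
    "residence": ["own_home", "sheltered_or_assisted", "long_term_care", "rehabilitation", "acute_ward"],
    "mobility": ["no_aids", "one_aid", "two_aids_or_frame", "requires_accompaniment", "unable_to_walk"],
    "mental_status": ["alert", "slight_confusion"],
    "fracture_type": ["femoral_neck", "pertrochanteric", "subtrochanteric", "pathological"],
    "malignancy": ["none", "skin", "other", "metastatic"]
  }
}
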