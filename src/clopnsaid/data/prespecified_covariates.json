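[
  {"name": "age", "source": "demographic", "coding": "continuous", "definition": {"field": "age"}},
  {"name": "female", "source": "demographic", "coding": "binary", "definition": {"field": "female"}},
  {"name": "race_black", "source": "demographic", "coding": "binary", "definition": {"field": "race_black"}},
  {"name": "race_hispanic_latino", "source": "demographic", "coding": "binary", "definition": {"field": "race_hispanic_latino"}},
  {"name": "race_other_unknown", "source": "demographic", "coding": "binary", "definition": {"field": "race_other_unknown"}},
  {"name": "state_CA", "source": "demographic", "coding": "binary", "definition": {"field": "state_CA"}},
  {"name": "state_FL", "source": "demographic", "coding": "binary", "definition": {"field": "state_FL"}},
  {"name": "state_NY", "source": "demographic", "coding": "binary", "definition": {"field": "state_NY"}},
  {"name": "state_OH", "source": "demographic", "coding": "binary", "definition": {"field": "state_OH"}},
  {"name": "any_hospitalization", "source": "utilization_count", "coding": "binary", "definition": {"setting": "inpatient", "unit": "claims", "min_count": 1}},
  {"name": "high_outpatient_use", "source": "utilization_count", "coding": "binary", "definition": {"setting": "outpatient", "unit": "claims", "min_count": 6}},
  {"name": "polypharmacy", "source": "utilization_count", "coding": "binary", "definition": {"unit": "dispensings", "min_count": 6}},
  {"name": "hypertension", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["4019", "401*"]}},
  {"name": "diabetes", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["250*"]}},
  {"name": "hyperlipidemia", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["272*"]}},
  {"name": "osteoarthritis", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["715*"]}},
  {"name": "rheumatoid_arthritis", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["714*"]}},
  {"name": "heart_failure", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["428*"]}},
  {"name": "prior_mi_history", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["412"]}},
  {"name": "peptic_ulcer_history", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["531.9*"]}},
  {"name": "renal_disease", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["585*"]}},
  {"name": "copd", "source": "diagnosis_flag", "coding": "binary", "definition": {"patterns": ["496"]}},
  {"name": "aspirin", "source": "drug_flag", "coding": "binary", "definition": {"ingredients": ["aspirin"]}},
  {"name": "statin", "source": "drug_flag", "coding": "binary", "definition": {"ingredients": ["simvastatin", "atorvastatin", "pravastatin"]}},
  {"name": "anticoagulant", "source": "drug_flag", "coding": "binary", "definition": {"ingredients": ["warfarin"]}},
  {"name": "ppi", "source": "drug_flag", "coding": "binary", "definition": {"ingredients": ["omeprazole", "pantoprazole"]}},
  {"name": "prior_ami_admission", "source": "prior_outcome_flag", "coding": "binary", "definition": {"outcome": "AMI"}},
  {"name": "prior_stroke_admission", "source": "prior_outcome_flag", "coding": "binary", "definition": {"outcome": "ischemic_stroke"}},
  {"name": "prior_gib_admission", "source": "prior_outcome_flag", "coding": "binary", "definition": {"outcome": "GIB"}},
  {"name": "prior_ich_admission", "source": "prior_outcome_flag", "coding": "binary", "definition": {"outcome": "ICH"}}
]
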