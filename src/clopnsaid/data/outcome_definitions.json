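{
  "AMI": {
    "description": "Acute myocardial infarction: principal or non-principal discharge diagnosis on inpatient claims.",
    "settings": ["inpatient"],
    "positions": "any_position",
    "include_patterns": ["410.*1"],
    "exclude_patterns": [],
    "injury_exclusion": null
  },
  "ischemic_stroke": {
    "description": "Ischemic stroke: principal discharge diagnosis on inpatient claims; admissions carrying an intracranial-injury code as a secondary diagnosis are excluded.",
    "settings": ["inpatient"],
    "positions": "principal_only",
    "include_patterns": ["433.*1", "434*", "436*"],
    "exclude_patterns": ["434.*0"],
    "injury_exclusion": {
      "patterns": ["800*", "801*", "802*", "803*", "804*", "850*", "851*", "852*", "853*", "854*"],
      "position_scope": "secondary"
    }
  },
  "GIB": {
    "description": "Gastrointestinal bleeding: principal or non-principal discharge diagnosis on inpatient claims.",
    "settings": ["inpatient"],
    "positions": "any_position",
    "include_patterns": [
      "530.21",
      "531.0*", "531.2*", "531.4*", "531.6*",
      "532.0*", "532.2*", "532.4*", "532.6*",
      "533.0*", "533.2*", "533.4*", "533.6*",
      "534.0*", "534.2*", "534.4*", "534.6*",
      "535.01", "535.11", "535.21", "535.31", "535.41", "535.51", "535.61", "535.71",
      "537.83", "537.84",
      "562.02", "562.03", "562.12", "562.13",
      "569.85", "569.86",
      "578.*"
    ],
    "exclude_patterns": [],
    "injury_exclusion": null
  },
  "ICH": {
    "description": "Intracranial hemorrhage (including hemorrhagic stroke): principal or non-principal diagnosis on inpatient or emergency-department claims; admissions carrying an intracranial-injury code in any position are excluded.",
    "settings": ["inpatient", "emergency_department"],
    "positions": "any_position",
    "include_patterns": ["430", "431"],
    "exclude_patterns": [],
    "injury_exclusion": {
      "patterns": ["800*", "801*", "802*", "803*", "804*", "850*", "851*", "852*", "853*", "854*"],
      "position_scope": "any"
    }
  }
}
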