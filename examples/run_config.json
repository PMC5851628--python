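{
  "seed": 11,
  "sim": {
    "n_persons": 5000,
    "true_hr": {"celecoxib": {"gib_ich": 2.0}, "naproxen": {"gib_ich": 0.7}}
  },
  "grace_days": 15,
  "baseline_days": 365,
  "hdps_top_k": 60,
  "hdps_top_n": 10,
  "hdps_min_exposed": 10,
  "n_strata": 10,
  "balance_threshold": 0.1,
  "censor_sensitivity_day": 180,
  "variants": ["primary", "age_lt65", "age_ge65", "sens_180d"]
}
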