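[
  {"_comment": "SYNTHETIC PLACEHOLDER coefficients, not estimated from any dataset. Replace with coefficients fit on real claims data before clinical use. Orientation: positive eta raises P(poor 1-year adherence); beta_mpr < 0 encodes that higher early MPR lowers risk, beta_age < 0 that older patients in these chronic classes adhere somewhat better.",
   "drug_class": "antihyperlipidemics", "prediction_day": 60,  "intercept": 2.0, "beta_age": -0.02, "beta_mpr": -2.5},
  {"drug_class": "antihyperlipidemics", "prediction_day": 90,  "intercept": 2.2, "beta_age": -0.02, "beta_mpr": -3.0},
  {"drug_class": "antihyperlipidemics", "prediction_day": 120, "intercept": 2.4, "beta_age": -0.02, "beta_mpr": -3.5},
  {"drug_class": "antihypertensives",   "prediction_day": 60,  "intercept": 1.8, "beta_age": -0.025, "beta_mpr": -2.5},
  {"drug_class": "antihypertensives",   "prediction_day": 90,  "intercept": 2.0, "beta_age": -0.025, "beta_mpr": -3.0},
  {"drug_class": "antihypertensives",   "prediction_day": 120, "intercept": 2.2, "beta_age": -0.025, "beta_mpr": -3.5},
  {"drug_class": "oral_hypoglycemics",  "prediction_day": 60,  "intercept": 1.9, "beta_age": -0.02, "beta_mpr": -2.4},
  {"drug_class": "oral_hypoglycemics",  "prediction_day": 90,  "intercept": 2.1, "beta_age": -0.02, "beta_mpr": -2.9},
  {"drug_class": "oral_hypoglycemics",  "prediction_day": 120, "intercept": 2.3, "beta_age": -0.02, "beta_mpr": -3.4}
]
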