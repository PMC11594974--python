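{
  "model": "weibull_aft",
  "comment": "Published two-center coefficient set (n=737 first allogeneic HSCTs, 294 deaths). Coefficients are log-days per unit covariate; covariance was not published, so interval-requiring operations must refit. Confidence bounds are recomputed from coefficient and standard error, never stored.",
  "coefficients": {
    "Intercept": 7.35820,
    "Diagnosis_2": 1.23406,
    "Diagnosis_3": 0.603906,
    "HLA_2": 0.267212,
    "HLA_3": -0.0726015,
    "AgePatient": 0.0164252,
    "AgeDonor": -0.0090390,
    "AgePatient:Diagnosis_2": -0.0189244,
    "AgePatient:Diagnosis_3": -0.0055234,
    "HLA_2:AgePatient": -0.0269508,
    "HLA_3:AgePatient": -0.0150409,
    "HLA_2:AgeDonor": 0.0231561,
    "HLA_3:AgeDonor": 0.0147905,
    "Diagnosis_2:AgeDonor": -0.0045711,
    "Diagnosis_3:AgeDonor": -0.0023857
  },
  "standard_errors": {
    "Intercept": 0.239108,
    "Diagnosis_2": 0.516391,
    "Diagnosis_3": 0.271176,
    "HLA_2": 0.354110,
    "HLA_3": 0.292851,
    "AgePatient": 0.0076519,
    "AgeDonor": 0.0077637,
    "AgePatient:Diagnosis_2": 0.0079260,
    "AgePatient:Diagnosis_3": 0.0050316,
    "HLA_2:AgePatient": 0.0092053,
    "HLA_3:AgePatient": 0.0078692,
    "HLA_2:AgeDonor": 0.0099341,
    "HLA_3:AgeDonor": 0.0074005,
    "Diagnosis_2:AgeDonor": 0.0072265,
    "Diagnosis_3:AgeDonor": 0.0050394
  },
  "shape": 1.69843,
  "shape_standard_error": 0.0654468,
  "covariance": null,
  "n": 737,
  "n_events": 294
}
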