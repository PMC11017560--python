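# Simulation-scenario registry for the enamel-hypoplasia (EH) individual-defect
# model: generating coefficients (log-odds scale, one column per tooth region in
# the order cervical, middle, incisal) and generating covariance matrices.
# Scenarios 1 and 2 share the full-model posterior-mean coefficients; Scenario 2
# makes the regions independent (identity covariance); Scenario 3 keeps the
# Scenario-1 covariance but zeroes all but a sparse set of coefficients.
# The OP / PEB / DC analogues live in supplementary material that is not
# redistributed here: those presets require user-supplied tables.

covariates: &eh_covariates
  - {name: child_oh2d, kind: continuous, dist: normal}
  - {name: child_ca, kind: continuous, dist: normal}
  - {name: child_p, kind: continuous, dist: normal}
  - {name: gestational_age, kind: continuous, dist: normal}
  - {name: formula, kind: binary, dist: bernoulli, p: 0.5}
  - {name: mother_age, kind: continuous, dist: normal}
  - {name: mother_bmi, kind: continuous, dist: normal}
  - {name: antacid_counts, kind: continuous, dist: normal}
  - {name: mother_ca_12wk, kind: continuous, dist: normal}
  - {name: mother_ca_28wk, kind: continuous, dist: normal}
  - {name: mother_ca_36wk, kind: continuous, dist: normal}
  - {name: mother_p_12wk, kind: continuous, dist: normal}
  - {name: mother_p_28wk, kind: continuous, dist: normal}
  - {name: mother_p_36wk, kind: continuous, dist: normal}
  - {name: child_fvdd, kind: continuous, dist: normal}
  - {name: mother_fvdd_12wk, kind: continuous, dist: normal}
  - {name: mother_fvdd_28wk, kind: continuous, dist: normal}
  - {name: mother_fvdd_36wk, kind: continuous, dist: normal}
  - {name: vdbp, kind: categorical3, dist: categorical, levels: ["1s", "1f", "2"]}
  - {name: child_age_visit, kind: continuous, dist: normal}
  - {name: child_dds, kind: binary, dist: bernoulli, p: 0.5}
  - {name: child_fltx, kind: binary, dist: bernoulli, p: 0.5}
  - {name: child_sex, kind: binary, dist: bernoulli, p: 0.5}
  - {name: child_strep_mutans, kind: continuous, dist: poisson, lam: 1.0, truncate: null}

race:
  name: maternal_race
  levels: [African American, Caucasian, Hispanic]

coefficients_full: &eh_full_coefficients
  intercept: [-1.235, -2.132, -0.383]
  child_oh2d: [0.001, 0.007, 0.014]
  child_ca: [0.129, 0.029, -0.067]
  child_p: [-0.167, -0.071, -0.171]
  gestational_age: [0.026, -0.04, -0.198]
  formula: [-0.443, -0.101, -0.007]
  mother_age: [0.036, 0.009, -0.009]
  mother_bmi: [0.055, -0.291, -0.174]
  antacid_counts: [-0.058, -0.097, -0.121]
  mother_ca_12wk: [-0.046, 0.052, 0.064]
  mother_ca_28wk: [-0.013, -0.067, -0.312]
  mother_ca_36wk: [0.084, 0.11, -0.06]
  mother_p_12wk: [0.064, -0.293, -0.003]
  mother_p_28wk: [0.052, 0.028, -0.059]
  mother_p_36wk: [0.398, 0.081, 0.007]
  child_fvdd: [0.014, -0.001, 0.009]
  mother_fvdd_12wk: [-1.003, -0.105, -0.092]
  mother_fvdd_28wk: [0.118, -0.011, -0.046]
  mother_fvdd_36wk: [-0.043, -0.015, -0.047]
  "vdbp[1f]": [-0.061, -0.173, -0.106]
  "vdbp[2]": [-0.023, 0.058, -0.073]
  child_age_visit: [0.628, 0.12, 0.297]
  child_dds: [-0.332, -0.278, -0.121]
  child_fltx: [-0.001, 0.173, -0.101]
  child_sex: [0.01, -0.039, 0.003]
  child_strep_mutans: [0.036, 0.692, -0.003]

covariance_application: &eh_application_cov
  - [1.0000, 0.1685, 0.0715]
  - [0.1685, 0.8601, 0.0200]
  - [0.0715, 0.0200, 0.7311]

scenarios:
  EH_s1:
    axis_kind: regions
    n: 148
    iterations: 50
    coefficients: *eh_full_coefficients
    covariance: *eh_application_cov
    covariates: *eh_covariates
  EH_s2:
    axis_kind: regions
    n: 148
    iterations: 50
    coefficients: *eh_full_coefficients
    covariance:
      - [1.0, 0.0, 0.0]
      - [0.0, 1.0, 0.0]
      - [0.0, 0.0, 1.0]
    covariates: *eh_covariates
  EH_s3:
    axis_kind: regions
    n: 148
    iterations: 50
    coefficients:
      intercept: [0.5, 0.25, 0.75]
      child_ca: [0.4, 0.8, 0.6]
      mother_age: [1.8, 0.6, 1.4]
      mother_p_28wk: [0.6, 0.4, 0.8]
      mother_fvdd_12wk: [0.45, 0.75, 0.65]
      "vdbp[1f]": [1.1, 0.9, 1.3]
      child_strep_mutans: [1.0, 2.0, 1.5]
    covariance: *eh_application_cov
    covariates: *eh_covariates
  # The following presets exist but require user-supplied supplementary
  # coefficient/covariance tables; PEB_s2 is deliberately absent (too few
  # outcomes of interest in two regions for the individual PEB model).
  OP_s1: {requires_supplement: true}
  OP_s2: {requires_supplement: true}
  OP_s3: {requires_supplement: true}
  PEB_s1: {requires_supplement: true}
  PEB_s3: {requires_supplement: true}
  DC_s1: {requires_supplement: true}
  DC_s2: {requires_supplement: true}
  DC_s3: {requires_supplement: true}
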