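# Default covariate registry for the univariate survival screen and the
# multivariable model. Columns refer to the analysis frame built by
# dasikit.report.analysis_frame. Right-skewed markers are natural-log
# transformed (length of stay as log(x+1): zero-day stays occur); the
# near-duplicate inflammation markers share a collinear group whose
# representative (NLR) is the only member carried into multivariable models.
# Forced covariates enter the multivariable model regardless of the screen.
covariates:
  - {name: readmission,       column: readmitted_30d,            kind: binary, forced: true}
  - {name: sex,               column: sex,                       kind: categorical, reference: male}
  - {name: age,               column: age,                       kind: numeric}
  - {name: marital_status,    column: marital_status,            kind: categorical, reference: married}
  - {name: language,          column: language,                  kind: categorical, reference: english}
  - {name: race,              column: race,                      kind: categorical, reference: white}
  - {name: fall_risk,         column: fall_risk,                 kind: categorical, reference: high}
  - {name: ecog,              column: ecog_ps,                   kind: numeric}
  - {name: admission_reason,  column: admission_reason,          kind: categorical, reference: pain}
  - {name: cancer_type,       column: cancer_type,               kind: categorical, reference: lung, forced: true}
  - {name: dasi_category,     column: dasi_category,             kind: categorical, reference: low, screen_only: true}
  - {name: metastasis,        column: metastasis,                kind: binary}
  - {name: healthcare_visits, column: healthcare_visits_6mo,     kind: numeric, forced: true}
  - {name: weight,            column: weight_kg,                 kind: numeric}
  - {name: height,            column: height_cm,                 kind: numeric}
  - {name: corrected_calcium, column: corrected_calcium,         kind: numeric, log_transform: true}
  - {name: creatinine,        column: creatinine,                kind: numeric, log_transform: true}
  - {name: length_of_stay,    column: length_of_index_admission, kind: numeric, log_transform: true, log_plus_one: true}
  - {name: hemoglobin,        column: hemoglobin,                kind: numeric}
  - {name: lymphocytes,       column: lymphocytes,               kind: numeric}
  - {name: nlr,               column: nlr,                       kind: numeric, log_transform: true, collinear_group: inflammation, representative: true}
  - {name: neutrophils,       column: neutrophils,               kind: numeric, log_transform: true, collinear_group: inflammation}
  - {name: plr,               column: plr,                       kind: numeric, log_transform: true, collinear_group: inflammation}
  - {name: platelets,         column: platelets,                 kind: numeric, log_transform: true, collinear_group: inflammation}
  - {name: sii,               column: sii,                       kind: numeric, log_transform: true, collinear_group: inflammation}
  - {name: albumin,           column: albumin,                   kind: numeric}
  - {name: pni,               column: pni,                       kind: numeric}
  - {name: sodium,            column: sodium,                    kind: numeric}
  - {name: wbc,               column: wbc,                       kind: numeric, log_transform: true}
  - {name: medications,       column: n_medications,             kind: numeric}
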