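# Deficit-accumulation factor registry: 23 binary deficits with their adverse
# cutoffs. A deficit fires only when the adverse rule matches literally; a
# value exactly at a strict (">"/"<") boundary scores 0. The corrected-calcium
# cutoff is inclusive (>= 11). Cutoffs are configuration so sensitivity
# analyses can vary them; these defaults are the frozen clinical registry.
#
# kind: where the value lives — record field, lab panel, or derived index.
# ops: is_true | gt | lt | ge | in_set | outside (lo/hi band, deficit outside).
factors:
  - {name: readmission,        kind: record, source: readmitted_30d,            rule: {op: is_true},                              units: flag}
  - {name: marital_support,    kind: record, source: marital_status,            rule: {op: in_set, values: [single, divorced, widowed]}, units: category}
  - {name: language,           kind: record, source: language,                  rule: {op: in_set, values: [not_english]},        units: category}
  - {name: fall_risk,          kind: record, source: fall_risk,                 rule: {op: in_set, values: [high]},               units: category}
  - {name: healthcare_visits,  kind: record, source: healthcare_visits_6mo,     rule: {op: gt, threshold: 2},                     units: count}
  - {name: bmi,                kind: index,  source: bmi,                       rule: {op: lt, threshold: 19},                    units: kg/m^2}
  - {name: corrected_calcium,  kind: lab,    source: corrected_calcium,         rule: {op: ge, threshold: 11},                    units: mg/dL}
  - {name: creatinine,         kind: lab,    source: creatinine,                rule: {op: gt, threshold: 1.3},                   units: mg/dL}
  - {name: ecog,               kind: record, source: ecog_ps,                   rule: {op: in_set, values: [2, 3, 4]},            units: grade}
  - {name: nlr,                kind: index,  source: nlr,                       rule: {op: gt, threshold: 5},                     units: ratio}
  - {name: neutrophils,        kind: lab,    source: neutrophils,               rule: {op: lt, threshold: 1.8},                   units: k/uL}
  - {name: plr,                kind: index,  source: plr,                       rule: {op: gt, threshold: 250},                   units: ratio}
  - {name: platelets,          kind: lab,    source: platelets,                 rule: {op: outside, lo: 150, hi: 450},            units: k/uL}
  - {name: hemoglobin,         kind: lab,    source: hemoglobin,                rule: {op: lt, threshold: 12},                    units: g/dL}
  - {name: length_of_stay,     kind: record, source: length_of_index_admission, rule: {op: gt, threshold: 5},                     units: days}
  - {name: lymphocytes,        kind: lab,    source: lymphocytes,               rule: {op: lt, threshold: 1.1},                   units: k/uL}
  - {name: sii,                kind: index,  source: sii,                       rule: {op: gt, threshold: 1600},                  units: index}
  - {name: albumin,            kind: lab,    source: albumin,                   rule: {op: lt, threshold: 3.5},                   units: g/dL}
  - {name: sodium,             kind: lab,    source: sodium,                    rule: {op: lt, threshold: 135},                   units: mmol/L}
  - {name: wbc,                kind: lab,    source: wbc,                       rule: {op: gt, threshold: 11},                    units: k/uL}
  - {name: medications,        kind: record, source: n_medications,             rule: {op: gt, threshold: 5},                     units: count}
  - {name: pni,                kind: index,  source: pni,                       rule: {op: lt, threshold: 45},                    units: index}
  - {name: metastasis,         kind: record, source: metastasis,                rule: {op: is_true},                              units: flag}
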