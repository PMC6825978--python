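# Admission-reason grouping lexicon: category -> case-insensitive substrings.
# First category (top-to-bottom) containing a matching keyword wins; anything
# unmatched is grouped as "other". Edit or pass a custom table to
# group_admission_reason to change the grouping.
chemo_side_effect:
  - chemotherapy side effect
  - nausea
  - vomiting
  - emesis
  - diarrhea
dehydration:
  - dehydration
  - dehydrated
fever:
  - fever
  - febrile
  - neutropenic fever
dyspnea:
  - dyspnea
  - shortness of breath
  - hypoxia
  - breathless
neurologic:
  - syncope
  - dizziness
  - headache
  - diplopia
  - ataxia
  - seizure
  - neurological
abnormal_findings:
  - abnormal
  - ekg
  - electrocardiogram
  - lab value
  - laboratory value
  - imaging
  - radiograph
pain:
  - pain
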