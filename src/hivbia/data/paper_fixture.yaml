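schema_version: 1
population:
  national_population: 48610288
  hiv_prevalence: 0.0031
  diagnosed_fraction: 0.925
  recent_fraction: 0.396
  annual_mortality: 0.0207
cohorts:
- label: recent
  size_2024: 55198.44033264001
  mean_age_2024: 34.0
- label: longstanding
  size_2024: 84191.56050736
  mean_age_2024: 48.0
comorbidity_epi:
- comorbidity: cardiovascular
  cohort: recent
  baseline_prevalence: 0.04800860285237079
  incidence_young: 0.0076461462886072695
  incidence_old: 0.0076461462886072695
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: renal
  cohort: recent
  baseline_prevalence: 0.023007896461324867
  incidence_young: 0.0037723545101471245
  incidence_old: 0.0037723545101471245
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: bone
  cohort: recent
  baseline_prevalence: 0.06900557293006805
  incidence_young: 0.013701696821954101
  incidence_old: 0.013701696821954101
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: neuropsychiatric
  cohort: recent
  baseline_prevalence: 0.04500127150388265
  incidence_young: 0.009132095670793205
  incidence_old: 0.009132095670793205
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: cardiovascular
  cohort: longstanding
  baseline_prevalence: 0.17100288809519593
  incidence_young: 0.02573963307077065
  incidence_old: 0.03860944960615598
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: renal
  cohort: longstanding
  baseline_prevalence: 0.07700296752942663
  incidence_young: 0.009493431367445737
  incidence_old: 0.014240147051168606
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: bone
  cohort: longstanding
  baseline_prevalence: 0.1650046621809031
  incidence_young: 0.02154975029407069
  incidence_old: 0.032324625441106036
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
- comorbidity: neuropsychiatric
  cohort: longstanding
  baseline_prevalence: 0.16299733509275363
  incidence_young: 0.015282881853636354
  incidence_old: 0.02292432278045453
  age_threshold: 50.0
  annual_incidence_reduction: 0.01
resources:
  cardiovascular:
    hospital_admissions: 0.63
    diagnostic_tests: 3.88
    ed_visits: 1.31
    outpatient_visits: 1.62
    hiv_visits: 3.21
    blood_tests: 9.2
  renal:
    hospital_admissions: 0.84
    diagnostic_tests: 4.6
    ed_visits: 1.98
    outpatient_visits: 1.72
    hiv_visits: 3.06
    blood_tests: 8.64
  bone:
    hospital_admissions: 0.32
    diagnostic_tests: 3.23
    ed_visits: 0.8
    outpatient_visits: 1.3
    hiv_visits: 2.9
    blood_tests: 7.85
  neuropsychiatric:
    hospital_admissions: 0.83
    diagnostic_tests: 4.24
    ed_visits: 1.95
    outpatient_visits: 1.67
    hiv_visits: 3.02
    blood_tests: 8.43
econ:
  unit_costs:
    hospital_admissions:
      cost: 4669.0
      origin_year: 2024
    diagnostic_tests:
      cost: 157.23
      origin_year: 2024
    ed_visits:
      cost: 225.93
      origin_year: 2024
    outpatient_visits:
      cost: 158.21
      origin_year: 2024
    hiv_visits:
      cost: 158.21
      origin_year: 2024
    blood_tests:
      cost: 30.96
      origin_year: 2024
  cpi_index:
    2024: 100.0
  discount_rate: 0.03
  base_year: 2024
  horizon:
  - 2024
  - 2034
scenarios:
- name: cardiovascular_darunavir
  source: expert
  deltas:
  - comorbidity: cardiovascular
    cohort: longstanding
    pp: 1.88
  - comorbidity: cardiovascular
    cohort: recent
    pp: 1.13
- name: renal_tenofovir_disoproxil
  source: expert
  deltas:
  - comorbidity: renal
    cohort: longstanding
    pp: 7.23
  - comorbidity: renal
    cohort: recent
    pp: 2.93
- name: bone_tenofovir_disoproxil
  source: expert
  deltas:
  - comorbidity: bone
    cohort: longstanding
    pp: 4.66
  - comorbidity: bone
    cohort: recent
    pp: 2.38
- name: neuropsychiatric_dolutegravir_expert
  source: expert
  deltas:
  - comorbidity: neuropsychiatric
    cohort: longstanding
    pp: 2.05
  - comorbidity: neuropsychiatric
    cohort: recent
    pp: 1.88
- name: neuropsychiatric_bictegravir_expert
  source: expert
  deltas:
  - comorbidity: neuropsychiatric
    cohort: longstanding
    pp: 2.0
  - comorbidity: neuropsychiatric
    cohort: recent
    pp: 1.25
- name: neuropsychiatric_dolutegravir_literature
  source: literature
  deltas:
  - comorbidity: neuropsychiatric
    cohort: longstanding
    pp: 2.58
  - comorbidity: neuropsychiatric
    cohort: recent
    pp: 2.58
- name: neuropsychiatric_bictegravir_literature
  source: literature
  deltas:
  - comorbidity: neuropsychiatric
    cohort: longstanding
    pp: 0.7
  - comorbidity: neuropsychiatric
    cohort: recent
    pp: 0.7
update_rule: at-risk
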