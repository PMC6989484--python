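# Default synthetic-cohort configuration.
#
# Anchors (means, SDs, prevalences, medians) are the published control-group
# baseline values of the population this package models; age slopes are
# calibration parameters set to (positive-group mean - control mean) divided
# by the groups' age gap (~10.9 years), so the generated group contrasts
# arise through age. See docs/methods.md for the calibration rationale.

n_subjects: 2542
seed: 0
age_mean: 60.9
age_sd: 9.1
age_range: [45.0, 95.0]
female_fraction: 0.556
followup_mean: 5.7
followup_sd: 0.6

# annual g-change model: d = base - slope*(age - age_mean) + N(0, noise_sd)
decline_base_per_year: -0.02
decline_slope_per_year_of_age: 0.005
decline_noise_sd: 0.07

# loadings +-0.612 make the first principal component of the five tests
# explain ~50% of their variance; time-scored tests load negatively.
tests:
  - {name: stroop_interference, loading: -0.612, age_slope: 0.90, mean: 44.0, sd: 13.0}
  - {name: ldst, loading: 0.612, age_slope: -0.23, mean: 32.2, sd: 6.2}
  - {name: word_fluency, loading: 0.612, age_slope: -0.055, mean: 23.8, sd: 5.7}
  - {name: wlt_delayed_recall, loading: 0.612, age_slope: -0.028, mean: 8.2, sd: 2.8}
  - {name: purdue_pegboard, loading: 0.612, age_slope: -0.055, mean: 10.9, sd: 1.7}

biomarkers:
  # cognitive tests beyond the g-factor battery
  - {name: mmse, category_path: cognitive_tests/mmse, dist: normal, mean: 28.4, sd: 1.5, age_slope: -0.055}
  - {name: subjective_memory_complaints, category_path: cognitive_tests/subjective_complaints, dist: binary, mean: 0.25, age_slope: 0.03}
  # demographics / genetics
  - {name: education, category_path: education, dist: ordinal, mean: 3.3, sd: 1.5, age_slope: -0.02, levels: [1, 7]}
  - {name: apoe_e4, category_path: genetics, dist: binary, mean: 0.283, age_slope: 0.008}
  # cardiovascular risk factors
  - {name: systolic_bp, category_path: cardiovascular, dist: normal, mean: 135.9, sd: 19.6, age_slope: 0.94}
  - {name: diastolic_bp, category_path: cardiovascular, dist: normal, mean: 82.4, sd: 10.6, age_slope: 0.04}
  - {name: bp_lowering_medication, category_path: cardiovascular, dist: binary, mean: 0.119, age_slope: 0.14}
  - {name: bmi, category_path: cardiovascular, dist: normal, mean: 27.4, sd: 4.1, age_slope: 0.07}
  - {name: total_cholesterol, category_path: cardiovascular, dist: normal, mean: 5.6, sd: 1.1, age_slope: -0.018}
  - {name: hdl_cholesterol, category_path: cardiovascular, dist: normal, mean: 1.5, sd: 0.4, age_slope: 0.009}
  - {name: lipid_lowering_medication, category_path: cardiovascular, dist: binary, mean: 0.213, age_slope: 0.06}
  - {name: smoking, category_path: cardiovascular, dist: ordinal, mean: 0.9, sd: 0.75, age_slope: -0.005, levels: [0, 2]}
  - {name: diabetes, category_path: cardiovascular, dist: binary, mean: 0.092, age_slope: 0.072}
  - {name: alcohol_per_week, category_path: cardiovascular, dist: lognormal, mean: 4.0, sd: 0.9, age_slope: -0.04}
  # gait factors (principal-component gait summaries; unit scale)
  - {name: gait_pace, category_path: gait, dist: normal, mean: 0.0, sd: 1.0, age_slope: -0.035}
  - {name: gait_rhythm, category_path: gait, dist: normal, mean: 0.0, sd: 1.0, age_slope: -0.012}
  - {name: gait_variability, category_path: gait, dist: normal, mean: 0.0, sd: 1.0, age_slope: 0.018}
  # MRI features
  - {name: intracranial_volume, category_path: mri, dist: normal, mean: 1144.0, sd: 113.0, age_slope: -0.06}
  - {name: white_matter_volume, category_path: mri/tissue_volumes, dist: normal, mean: 419.0, sd: 57.0, age_slope: -2.66}
  - {name: gray_matter_volume, category_path: mri/tissue_volumes, dist: normal, mean: 537.0, sd: 52.0, age_slope: -1.38}
  - {name: csf_volume, category_path: mri/tissue_volumes, dist: normal, mean: 186.0, sd: 46.0, age_slope: 3.39}
  - {name: hippocampus_volume, category_path: mri/region_volumes, dist: normal, mean: 6.8, sd: 0.7, age_slope: -0.037}
  - {name: white_matter_lesion_volume, category_path: mri/lesions, dist: lognormal, mean: 2.4, sd: 0.83, age_slope: 0.067}
  - {name: cerebral_microbleeds, category_path: mri/lesions, dist: binary, mean: 0.156, age_slope: 0.053}
  - {name: lacunar_infarcts, category_path: mri/lesions, dist: binary, mean: 0.030, age_slope: 0.089}
  - {name: global_fa, category_path: mri/diffusion, dist: normal, mean: 0.30, sd: 0.015, age_slope: -0.0005}
  - {name: global_md, category_path: mri/diffusion, dist: normal, mean: 0.70, sd: 0.03, age_slope: 0.0092}
  - {name: global_cortical_thickness, category_path: mri/cortical_thickness, dist: normal, mean: 2.5, sd: 0.1, age_slope: -0.0092}
  - {name: cerebral_blood_flow, category_path: mri/flow, dist: normal, mean: 500.0, sd: 90.0, age_slope: -2.0}

# MCAR missingness emulating incomplete ascertainment in a population study
missing_rates:
  global_fa: 0.03
  global_md: 0.03
  cerebral_blood_flow: 0.10
  gait_pace: 0.05
  gait_rhythm: 0.05
  gait_variability: 0.05
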