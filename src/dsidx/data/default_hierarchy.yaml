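# Default feature hierarchy. Top level: age, sex, education, genetics,
# cognitive tests, cardiovascular risk factors, gait, MRI features.
# Lower levels group features the way the default generator's category
# paths do; prune_hierarchy() restricts it to any feature subset.
name: dsi
children:
  - feature: age
  - feature: sex
  - feature: education
  - name: genetics
    children:
      - feature: apoe_e4
  - name: cognitive_tests
    children:
      - name: objective_tests
        children:
          - feature: stroop_interference
          - feature: ldst
          - feature: word_fluency
          - feature: wlt_delayed_recall
          - feature: purdue_pegboard
      - feature: mmse
      - feature: subjective_memory_complaints
  - name: cardiovascular
    children:
      - feature: systolic_bp
      - feature: diastolic_bp
      - feature: bp_lowering_medication
      - feature: bmi
      - feature: total_cholesterol
      - feature: hdl_cholesterol
      - feature: lipid_lowering_medication
      - feature: smoking
      - feature: diabetes
      - feature: alcohol_per_week
  - name: gait
    children:
      - feature: gait_pace
      - feature: gait_rhythm
      - feature: gait_variability
  - name: mri
    children:
      - feature: intracranial_volume
      - name: tissue_volumes
        children:
          - feature: white_matter_volume
          - feature: gray_matter_volume
          - feature: csf_volume
      - name: region_volumes
        children:
          - feature: hippocampus_volume
      - name: lesions
        children:
          - feature: white_matter_lesion_volume
          - feature: cerebral_microbleeds
          - feature: lacunar_infarcts
      - name: diffusion
        children:
          - feature: global_fa
          - feature: global_md
      - feature: global_cortical_thickness
      - feature: cerebral_blood_flow
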