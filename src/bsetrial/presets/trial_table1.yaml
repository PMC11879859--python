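# Trial calibration preset: baseline marginals match the published baseline
# table (mixture means: glucose 6.4 mmol/l, BMI 32.1 kg/m2, insulin 18.9
# mIE/l, C-peptide 1.22 nmol/l); cluster mix matches the observed trial
# counts 51/19/19 (MARD/SIRD/MOD of 89); BSE effect 0.4 mmol/l in the
# MARD-like cluster only; SD of 12-week glucose change 0.63 mmol/l.
name: trial_table1
n_per_arm: [44, 45]
placebo_change_mean: 0.1
change_sd: 0.63
dropout_rate: 0.0
effect_by_cluster:
  MARD-like: 0.4
  SIRD-like: 0.0
  MOD-like: 0.0
  SIDD-like: 0.0
clusters:
  MARD-like:
    weight: 0.5730337078651685
    means: {glucose: 6.33, insulin: 15.0, c_peptide: 1.00, hba1c: 37.5, bmi: 30.13, age: 70.0}
    sds:   {glucose: 0.18, insulin: 6.0,  c_peptide: 0.15, hba1c: 2.0,  bmi: 2.0,   age: 6.0}
  SIRD-like:
    weight: 0.2134831460674157
    means: {glucose: 6.55, insulin: 28.0, c_peptide: 1.75, hba1c: 38.8, bmi: 35.0,  age: 63.0}
    sds:   {glucose: 0.18, insulin: 6.0,  c_peptide: 0.15, hba1c: 2.0,  bmi: 2.0,   age: 6.0}
  MOD-like:
    weight: 0.2134831460674157
    means: {glucose: 6.44, insulin: 20.4, c_peptide: 1.30, hba1c: 38.2, bmi: 34.5,  age: 49.0}
    sds:   {glucose: 0.18, insulin: 6.0,  c_peptide: 0.15, hba1c: 2.0,  bmi: 2.0,   age: 6.0}
  SIDD-like:
    weight: 0.0
    means: {glucose: 6.80, insulin: 8.0,  c_peptide: 0.55, hba1c: 44.0, bmi: 27.0,  age: 45.0}
    sds:   {glucose: 0.18, insulin: 6.0,  c_peptide: 0.15, hba1c: 2.0,  bmi: 2.0,   age: 6.0}
reference_mix:
  MARD-like: 0.40
  SIRD-like: 0.22
  MOD-like: 0.22
  SIDD-like: 0.16
n_reference: 8980
sulforaphane:
  mean_low: 0.2
  mean_high: 1.3
  common_sd: 0.55
  weight_high: 0.5
bt2160:
  mode: strata
  mean_high: 0.032
  mean_low: 0.022
  sigma_log: 0.5
  spearman_target: -0.47
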