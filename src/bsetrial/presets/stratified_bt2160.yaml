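# Stratified BT2160-interaction preset: a single lognormal BT2160 marginal
# (abundance does not differ between clusters) with a within-MARD latent
# copula chosen so that, among BSE recipients with above-median BT2160
# abundance, the MARD-vs-pooled-others improvement contrast is 0.7 mmol/l
# (base cluster difference 0.35 + dependence term 0.35) while the
# below-median contrast is ~0.
extends: trial_table1
name: stratified_bt2160
effect_by_cluster:
  MARD-like: 0.35
  SIRD-like: 0.0
  MOD-like: 0.0
  SIDD-like: 0.0
bt2160:
  mode: single
  mean: 0.027
  sigma_log: 0.5
  above_median_contrast: 0.7
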