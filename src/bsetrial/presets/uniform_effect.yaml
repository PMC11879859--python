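# Uniform-effect variant of the trial preset: every cluster receives the
# same 0.2 mmol/l BSE-minus-placebo reduction (the trial's overall effect).
extends: trial_table1
name: uniform_effect
effect_by_cluster:
  MARD-like: 0.2
  SIRD-like: 0.2
  MOD-like: 0.2
  SIDD-like: 0.2
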