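# BT2160 strata preset: lognormal operon abundance with stratum means 0.032
# (high serum sulforaphane) and 0.022 (low), and a Gaussian-copula
# dependence on glycaemic improvement in MARD-like BSE recipients
# rank-calibrated to Spearman -0.47.  Identical to trial_table1 apart from
# the name; kept as its own preset for the microbiome stages.
extends: trial_table1
name: bt2160
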