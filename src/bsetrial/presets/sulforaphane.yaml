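# Serum sulforaphane bimodal preset: two-component equal-variance Gaussian
# mixture with means 0.2 and 1.3 nmol/ml and common SD 0.55 (= half the
# mean separation, i.e. modes two common SDs apart), equal weights.
extends: trial_table1
name: sulforaphane
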