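# Unit parameters for exercising the model mechanics independently of
# any transcribed reference coefficients.
mode: bivariate
a_max: 1.0
k_r: 1.0
k_p: 1.0
provenance: synthetic unit parameters for testing; not physiological
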