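# Reference saturable-absorption parameters, mmol/day.
#
# Bivariate zinc-phytate form of the Miller/Krebs/Hambidge equilibrium
# model; values are the published 2007 coefficients of that model
# lineage (a_max = 0.13, k_r = 0.10, k_p = 1.2 mmol/day), transcribed
# here without refitting. Later trivariate refinements adjust a_max and
# k_p from daily protein and calcium; see model_trivariate_synthetic.yaml
# for the adjustment mechanism.
mode: bivariate
a_max: 0.13
k_r: 0.10
k_p: 1.2
provenance: >
  Saturable zinc-phytate absorption model (Miller, Krebs & Hambidge
  lineage), published bivariate coefficients in mmol/day.
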