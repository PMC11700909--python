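# SYNTHETIC trivariate example config.
#
# Demonstrates the calcium/protein adjustment mechanism: protein raises
# the absorptive ceiling (log-linear in g/day), calcium deepens phytate
# binding (log-linear in mmol/day, lowering k_p). The slopes below are
# illustrative magnitudes chosen to satisfy the physiological
# directionality constraints; they are NOT transcribed from any fitted
# model and must be replaced before quantitative use.
mode: trivariate
a_max: 0.13
k_r: 0.10
k_p: 1.2
coefficients:
  log_a_max_per_g_protein: 0.002
  log_k_p_per_mmol_calcium: -0.01
provenance: synthetic example of the covariate-adjustment mechanism; slopes illustrative only
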