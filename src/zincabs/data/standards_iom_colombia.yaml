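# Reference standards for adults 19-70 y, mg/day unless noted.
# RAZ: IOM required absorbed zinc. EAR/RDA: IOM and Colombian dietary
# reference intakes. iom_absorption_pct: IOM fractional absorption
# assumptions (%). pz_threshold: phytate:zinc molar ratio above which
# absorption is markedly impaired. phytate_reference_mg: US adult
# phytate intake reference used as a benchmark.
raz_male: 3.84
raz_female: 3.30
iom_ear_male: 9.4
iom_ear_female: 6.8
iom_rda_male: 11.0
iom_rda_female: 8.0
col_ear_male: 12.0
col_ear_female: 6.5
col_rda_male: 14.0
col_rda_female: 8.0
iom_absorption_pct_male: 41.0
iom_absorption_pct_female: 48.0
pz_threshold: 15.0
phytate_reference_mg: 710.0
provenance: IOM dietary reference intakes and Colombian national standards for zinc, adults
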