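# zincabs

Zinc absorption and dietary reference intake analysis for adult
nutrition surveys.

Dietary zinc is poorly absorbed from plant-heavy diets because phytate
(myo-inositol hexakisphosphate) chelates zinc in the gut lumen. For a
surveyed population this matters twice: intakes can fall below reference
values, and even adequate intakes can absorb poorly. `zincabs` is a
library plus CLI for nutrition scientists who have per-individual daily
intakes of zinc, phytate, protein and calcium (for example from a
24-hour-recall survey) and want, per individual and per sex × age
stratum:

* **absorbed zinc** — total (TAZ, mg/day) and fractional (FAZ) — from a
  saturable equilibrium absorption model;
* **model-based requirements** — EAR_M and RDA_M derived from FAZ and
  the required absorbed zinc (RAZ);
* **adequacy prevalence** — percentage of intakes below the IOM and
  Colombian EAR/RDA;
* **phytate:zinc molar-ratio screening** against the bioavailability
  threshold of 15;
* **benchmark statistics** — Wilcoxon one-sample comparisons of each
  metric against its reference value, with median (Q1, Q3) summaries.

Because survey microdata are often restricted, the package includes a
synthetic cohort generator whose stratum-wise intake quartiles are
calibrated to the published summaries of Colombia's ENSIN 2005 adult
survey, so the full pipeline is runnable and testable out of the box.

## The model

Absorption follows a saturable equilibrium response. With daily zinc
TDZ and phytate TDP in mmol/day,

```
B   = A_MAX + TDZ + K_R (1 + TDP / K_P)
TAZ = ( B − sqrt(B² − 4 A_MAX TDZ) ) / 2          FAZ = TAZ / TDZ
```

the physically admissible root of the equilibrium quadratic: absorption
rises with intake but saturates at `A_MAX`, and phytate depresses it
through the binding constant `K_P`. In trivariate mode, daily protein
raises `A_MAX` and daily calcium lowers `K_P` (competitive
co-precipitation with phytate) through configurable log-linear
adjustments whose directions are validated at load time.

Requirements follow from fractional absorption: with RAZ = 3.84 mg/day
(men) or 3.30 mg/day (women),

```
EAR_M = RAZ / FAZ(%) × 100          RDA_M = 1.2 × EAR_M
```

## Worked example

Run the whole pipeline on a synthetic cohort at the published stratum
sizes (12 987 adults):

```python
from zincabs import RunConfig, run_pipeline
import pandas as pd

paths = run_pipeline(RunConfig(out_dir="demo", seed=1))
t4 = pd.read_csv(paths["table4.csv"])
print(t4[["sex", "age_band", "n", "ear_iom", "ear_col",
          "ear_m_median_1dp", "rda_m_median_1dp"]].to_string(index=False))
```

```
   sex age_band    n  ear_iom  ear_col  ear_m_median_1dp  rda_m_median_1dp
  male    19-30 2754      9.4     12.0              11.7              14.1
  male    31-50 2431      9.4     12.0              11.3              13.6
  male    51-70  867      9.4     12.0              10.9              13.1
  male      all 6052      9.4     12.0              11.4              13.7
female    19-30 3057      6.8      6.5               9.0              10.8
female    31-50 2795      6.8      6.5               8.6              10.3
female    51-70 1083      6.8      6.5               8.4              10.1
female      all 6935      6.8      6.5               8.7              10.4
```

Model-derived requirements exceed the IOM EARs throughout — absorption
from this diet pattern is too low for the standard intakes to deliver
the required absorbed zinc — and for women exceed the Colombian EAR by
~2 mg/day. The adequacy table tells the intake side of the same story:

```
   sex age_band    n  pct_below_iom_ear_1dp  pct_below_col_rda_1dp
  male    19-30 2754                   59.9                   83.8
female    19-30 3057                   56.6                   67.4
```

about 60% of young men fall below the IOM EAR. The benchmark report
(`tests.csv`) confirms the phytate context: the population
phytate:zinc molar ratio sits significantly below the impairment
threshold of 15, and phytate intake significantly below the 710 mg/day
US reference (both Wilcoxon p < 0.001, direction "less").

The same analysis runs from the shell:

```
zincabs simulate --seed 1 --out cohort.csv
zincabs tables --in cohort.csv --out-dir demo
```

or on your own intake CSV with columns
`id,sex,age,zinc,phytate,protein,calcium` (mg/day except protein in
g/day; sex is M/F/male/female). Model parameters and reference
standards are YAML configs (`src/zincabs/data/`); pass alternates with
`--model-config` / `--standards-config`.

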