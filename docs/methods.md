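# Methods

## Absorption model

Zinc uptake is modelled as an equilibrium between luminal zinc, a
saturable absorptive pathway and phytate chelation. Writing TDZ and TDP
for daily zinc and phytate in mmol/day, total absorbed zinc is the
lower root of the equilibrium quadratic

    TAZ² − B·TAZ + A_MAX·TDZ = 0,   B = A_MAX + TDZ + K_R (1 + TDP/K_P),

taken in closed form as `TAZ = (B − √(B² − 4·A_MAX·TDZ))/2`. The
discriminant equals `(A_MAX − TDZ)² + 2k(A_MAX + TDZ) + k²` with
`k = K_R (1 + TDP/K_P) ≥ 0`, hence is non-negative for every valid
input; a negative discriminant can only come from a broken parameter
configuration, so the code raises instead of clamping. The root
satisfies `0 ≤ TAZ ≤ min(A_MAX, TDZ)`, is strictly increasing in TDZ
and strictly decreasing in TDP, and `FAZ = TAZ/TDZ` is strictly
decreasing in both — fractional absorption falls as intake rises, the
defining feature of a saturable response. At TDZ = 0 the fraction is
continued by its analytic limit `A_MAX / (A_MAX + K_R (1 + TDP/K_P))`
so stratum summaries remain total functions; such records are rare and
the ratio there multiplies a zero absorption anyway.

### Parameters

All three parameters are mmol/day and config-loaded, never hard-coded:

| parameter | meaning | reference default |
|---|---|---|
| `a_max` | maximal daily absorbable zinc (plateau) | 0.13 |
| `k_r` | zinc–receptor dissociation scale | 0.10 |
| `k_p` | zinc–phytate binding scale | 1.2 |

The defaults (`data/model_reference.yaml`) are the published bivariate
coefficients of the Miller/Krebs/Hambidge equilibrium-model lineage.
The later trivariate refinement of that lineage additionally lets
dietary protein and calcium move the parameters; its fitted
coefficients are not shipped here. Instead the package implements the
adjustment *mechanism* — per-individual log-linear multipliers

    A_MAX_i = a_max · exp(c_pr · TDPr_i)      (c_pr ≥ 0, per g protein)
    K_P_i   = k_p  · exp(c_ca · TDC_i)        (c_ca ≤ 0, per mmol calcium)

— with a load-time probe over a protein × calcium grid that rejects any
coefficient set under which more calcium could raise, or more protein
lower, FAZ. `data/model_trivariate_synthetic.yaml` demonstrates the
mechanism with illustrative slopes and is labelled synthetic; the test
suite exercises model mechanics with unit parameters
(`data/model_test.yaml`) so correctness is independent of any
transcription. None of the requirement-derivation results depend on
these coefficients: EAR_M/RDA_M are derived from FAZ, and the published
worked example feeds published FAZ values in directly.

Units: the model runs in mmol/day internally and mg/day at the API
boundary. Molar masses are phytic acid 660.04 g/mol and zinc
65.38 g/mol (IZiNCG convention, configurable — published population
medians cannot pin down which masses the original analysis used, so
the default is documented, not asserted); calcium uses 40.078 g/mol.

## Requirement derivation

`EAR_M = RAZ / FAZ(%) × 100` and `RDA_M = 1.2 × EAR_M`, with the IOM
required absorbed zinc RAZ = 3.84 mg/day (men) and 3.30 mg/day (women),
ages 19+. EAR_M/RDA_M are computed per individual and summarised
afterwards. Because the transform is strictly decreasing in FAZ, stratum
quantiles of EAR_M mirror those of FAZ with Q1 and Q3 swapped. The
mirror is exact whenever the quantile lands on an order statistic (all
odd-sized strata for the median; half-sizes odd for the hinges) and is
only approximate when a quantile is the average of two observations,
since the transform is nonlinear; at survey sample sizes the two paths
agree to well below reporting precision. Both paths are implemented and
the per-individual one is primary.

## Summaries and tests

* **Quantiles** use the median-of-halves (Tukey hinge) convention with
  averaging medians: the sample is split at the median, the median
  observation joins both halves when n is odd, and each quartile is the
  median of its half (Q1 of [1,2,3,4,5] is 2). Printed survey quartiles
  cannot disambiguate the original convention; this one is fixed and
  documented, and all cross-checks against published quartiles carry
  tolerances that absorb the difference.
* **Normality gate**: Shapiro–Wilk per stratum at α = 0.05, used only
  to justify the nonparametric summaries; samples above 5000 are
  reduced to a seeded subsample because the test's p-values degrade at
  larger n.
* **Benchmark tests**: Wilcoxon one-sample signed-rank, two-sided
  throughout, with the direction reported separately from the sign of
  the median difference. Observations exactly equal to the benchmark
  are dropped before ranking (Wilcoxon's original rule; the original
  analysis does not state its tie policy). The exact null distribution
  is used for untied samples up to n = 25, the normal approximation
  with continuity correction otherwise; at survey sizes every variant
  agrees far below the 0.001 reporting threshold. scipy provides the
  test statistic; an independent 2ⁿ sign-pattern enumeration serves as
  the oracle in the test suite.
* **Adequacy** uses strict `<` at each cutoff: a record exactly at the
  EAR is counted as meeting it. Ties are measure-zero for continuous
  intakes; the rule is documented because the source tables do not
  state one.
* Percentages and mg/day values are reported to one decimal; every
  output CSV carries full-precision columns with `*_1dp` companions so
  downstream checks never depend on display rounding.

## Synthetic survey generator

The generator emulates the marginal intake structure of the ENSIN 2005
adult strata from their published median (Q1, Q3): each nutrient is
lognormal with `location = ln(median)` (median matched exactly) and
`scale = ln(Q3/Q1) / (2·z₀.₇₅)`, which matches the printed quartile
*ratio*; the fitted Q1/Q3 are the symmetric-in-log (geometric-mean)
reconciliation of the printed, mildly asymmetric pair. Right-skewed
lognormals are the minimal faithful two-parameter choice for intake
data whose printed Q3 − median exceeds median − Q1 throughout and whose
normality was rejected in the original analysis.

Joint structure uses a Gaussian copula with Spearman rank correlations
(converted to Pearson via `2·sin(πρ/6)`): defaults 0.5 for zinc–protein
and zinc–phytate, 0.3 elsewhere — a plausible dietary co-consumption
pattern, clearly an assumption since no joint structure is published;
every correlation-sensitive check uses tolerant bounds. Ages are
uniform integers on the band; stratum sizes default to the published
counts (2754, 2431, 867, 3057, 2795, 1083). One master seed drives
everything, with independent per-stratum streams derived by stable
hashing (CRC-32 of the stratum label into a `SeedSequence`), so any
stratum regenerates identically in isolation.

What the generator does **not** emulate: the survey's sampling design
and weights, within-person day-to-day variance (usual-intake
deconvolution), the exact shape of the empirical distributions beyond
three quantiles, and the true inter-nutrient dependence. Passing
calibration therefore shows the pipeline reproduces the published
*stratum medians* (within 1% at n = 10⁵) and lands within a few
percentage points on threshold-crossing statistics (e.g. percent below
the IOM EAR), not that it reproduces the restricted microdata; extreme
quantities such as the published FAZ min/max are out of reach by
construction.

## Problem sizes and numerical choices

The default test run generates cohorts of 250–500 records per stratum
for pipeline mechanics, 10⁵ per stratum for calibration checks, and the
published sizes (12 987 total) for the survey-scale benchmark checks —
sizes chosen so each check is decisive at its stated tolerance.
Closed-form absorption is verified against 200-step bisection on the
bracketing interval `[0, min(A_MAX, TDZ)]` to 1e-9 mmol. The copula's
Pearson matrix receives a 1e-12 diagonal ridge before Cholesky
factorisation to tolerate rank correlations at ±1. Degenerate inputs
raise rather than warn: empty strata in summaries, constant samples in
Shapiro–Wilk, all-tied benchmark comparisons ("uninformative
comparison"), FAZ ≤ 0 in requirement derivation.

## Known limitations

* Trivariate covariate coefficients are illustrative, not fitted;
  quantitative trivariate use requires supplying fitted slopes in a
  model config.
* The EAR cut-point percentages apply no usual-intake correction, so
  they describe observed-day intakes exactly as the source tables do.
* Iron, gastric acidity and other absorption modifiers are outside the
  model's variable set (zinc, phytate, calcium, protein).
* Requirement derivation covers adults 19–70; children, pregnancy and
  lactation need different RAZ values and are not handled.
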