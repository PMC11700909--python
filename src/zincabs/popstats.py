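"""Stratified nonparametric summaries and one-sample benchmark tests.

Intake distributions in nutrition surveys are right-skewed, so the
pipeline summarises every metric as median (Q1, Q3) and compares
population medians to fixed benchmarks with the Wilcoxon one-sample
signed-rank test. A Shapiro–Wilk gate documents the non-normality that
justifies the nonparametric choice.

Quartiles use the median-of-halves ("hinge") convention: the sample is
split at the median, the median observation is included in both halves
when n is odd, and each quartile is the (averaging) median of its half.
This fixes Q1 of [1, 2, 3, 4, 5] at 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dri import DEFAULT_STANDARDS, ReferenceStandards
from .intake import AgeBand, Sex

ALPHA_DEFAULT = 0.05
ALPHA_STRICT = 0.001
#: Largest sample for which the exact signed-rank null is enumerated.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class StratumSummary:
    """Median (Q1, Q3) of one metric in one stratum, optional moments."""

    metric: str
    n: int
    median: float
    q1: float
    q3: float
    mean: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError(
                f"{self.metric}: quartiles out of order "
                f"({self.q1}, {self.median}, {self.q3})"
            )


@dataclass(frozen=True)
class TestResult:
    """One signed-rank comparison of a sample median with a benchmark."""

    metric: str
    stratum: str
    benchmark: float
    n: int
    statistic: float
    p_value: float
    alternative: str
    direction: str
    significant_05: bool
    significant_001: bool


def _median(sorted_values: np.ndarray) -> float:
    n = sorted_values.size
    mid = n // 2
    if n % 2:
        return float(sorted_values[mid])
    return float(0.5 * (sorted_values[mid - 1] + sorted_values[mid]))


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """(Q1, median, Q3) under the median-of-halves convention."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty sample")
    n = arr.size
    lower = arr[: n // 2 + (n % 2)]
    upper = arr[n // 2 :]
    return _median(lower), _median(arr), _median(upper)


def quartile_summary(
    values: Sequence[float], metric: str = "", extras: bool = False
) -> StratumSummary:
    """Median (Q1, Q3) summary; mean, SD (n−1), min, max when ``extras``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = tukey_hinges(arr)
    kwargs = {}
    if extras:
        kwargs = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return StratumSummary(metric=metric, n=int(arr.size), median=med, q1=q1, q3=q3, **kwargs)


def shapiro_gate(
    values: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
    max_n: int = 5000,
    seed: int = 0,
) -> dict:
    """Shapiro–Wilk normality gate for a stratum.

    Returns ``{"p_value", "normal", "n"}`` with ``normal = p >= alpha``.
    Samples larger than ``max_n`` (where the test's p-values lose
    accuracy) are reduced to a seeded random subsample. Constant
    samples and n < 3 are degenerate and raise.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    if arr.size > max_n:
        rng = np.random.default_rng(seed)
        arr = rng.choice(arr, size=max_n, replace=False)
    result = stats.shapiro(arr)
    return {"p_value": float(result.pvalue), "normal": bool(result.pvalue >= alpha), "n": int(arr.size)}


def wilcoxon_one_sample(
    values: Sequence[float],
    mu0: float,
    alternative: str = "two-sided",
    metric: str = "",
    stratum: str = "",
) -> TestResult:
    """Wilcoxon signed-rank test of H0: median == ``mu0``.

    Observations exactly equal to the benchmark are dropped before
    ranking (Wilcoxon's original rule). The exact null distribution is
    used for untied samples up to ``EXACT_N_MAX``; otherwise the normal
    approximation with continuity correction. Raises when every value
    ties with the benchmark (uninformative comparison).
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    diffs = np.asarray(values, dtype=float) - mu0
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError(
            f"uninformative comparison: every value equals the benchmark {mu0}"
        )
    has_ties = np.unique(np.abs(diffs)).size < n
    method = "exact" if (n <= EXACT_N_MAX and not has_ties) else "approx"
    res = stats.wilcoxon(
        diffs, alternative=alternative, correction=True, method=method
    )
    median_diff = float(np.median(diffs))
    direction = "less" if median_diff < 0 else ("greater" if median_diff > 0 else "equal")
    p = float(res.pvalue)
    return TestResult(
        metric=metric,
        stratum=stratum,
        benchmark=mu0,
        n=int(n),
        statistic=float(res.statistic),
        p_value=p,
        alternative=alternative,
        direction=direction,
        significant_05=p < ALPHA_DEFAULT,
        significant_001=p < ALPHA_STRICT,
    )


def benchmark_comparisons(
    cohort: pd.DataFrame, standards: ReferenceStandards = DEFAULT_STANDARDS
) -> list[TestResult]:
    """The full benchmark battery for an analysed cohort.

    ``cohort`` must already carry the derived columns ``age_band``,
    ``pz_ratio``, ``taz_mg``, ``faz``, ``ear_m`` and ``rda_m``. Runs,
    all two-sided:

    * per sex: TAZ vs the required absorbed zinc (RAZ); FAZ (%) vs the
      IOM absorption rate (41% men, 48% women);
    * per sex × age band: EAR_M vs the IOM and Colombian EARs, RDA_M vs
      both RDAs;
    * whole population: phytate:zinc ratio vs the bioavailability
      threshold (15); phytate intake vs the 710 mg/day reference.
    """
    results: list[TestResult] = []
    for sex in (Sex.MALE, Sex.FEMALE):
        sub = cohort[cohort["sex"] == sex.value]
        if sub.empty:
            continue
        results.append(
            wilcoxon_one_sample(
                sub["taz_mg"], standards.raz(sex), metric="taz_mg",
                stratum=f"{sex.value} all",
            )
        )
        results.append(
            wilcoxon_one_sample(
                100.0 * sub["faz"], standards.iom_absorption_pct(sex),
                metric="faz_pct", stratum=f"{sex.value} all",
            )
        )
        for band in (AgeBand.Y19_30, AgeBand.Y31_50, AgeBand.Y51_70):
            cell = sub[sub["age_band"] == band.value]
            if cell.empty:
                continue
            label = f"{sex.value} {band.value}"
            for source in ("iom", "col"):
                results.append(
                    wilcoxon_one_sample(
                        cell["ear_m"], standards.ear(source, sex),
                        metric=f"ear_m_vs_{source}_ear", stratum=label,
                    )
                )
                results.append(
                    wilcoxon_one_sample(
                        cell["rda_m"], standards.rda(source, sex),
                        metric=f"rda_m_vs_{source}_rda", stratum=label,
                    )
                )
    ratios = cohort["pz_ratio"].dropna()
    results.append(
        wilcoxon_one_sample(
            ratios, standards.pz_threshold, metric="pz_ratio", stratum="population"
        )
    )
    results.append(
        wilcoxon_one_sample(
            cohort["phytate_mg"], standards.phytate_reference_mg,
            metric="phytate_mg", stratum="population",
        )
    )
    return results


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
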