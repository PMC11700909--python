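"""Synthetic survey cohorts calibrated to published intake quartiles.

The restricted survey microdata are emulated by drawing, per sex × age
stratum, correlated lognormal nutrient intakes whose marginals are
fitted to the published median (Q1, Q3):

* location = ln(median)  — the median is matched exactly;
* scale = ln(Q3/Q1) / (2 * z_0.75) with z_0.75 = Phi^-1(0.75) ≈ 0.67449
  — the printed interquartile spread is matched as a symmetric-in-log
  compromise, so the fitted Q1/Q3 are a geometric-mean reconciliation
  of the printed (asymmetric) pair.

Joint structure across the four nutrients uses a Gaussian copula with a
configurable Spearman rank-correlation matrix (the survey publishes no
joint structure; defaults are a plausible dietary co-consumption
pattern and are clearly an assumption). Ages are uniform integers on
the band; generation is fully reproducible from one master seed, with
independent per-stratum streams derived by stable hashing so any
stratum can be regenerated alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ensin2005
from .intake import NUTRIENT_COLUMNS, AgeBand, Sex, StratumKey
from .popstats import tukey_hinges

#: Upper quartile of the standard normal, used in the quartile fit.
Z75 = float(stats.norm.ppf(0.75))

#: Default Spearman rank correlations between daily nutrient intakes
#: (zinc, phytate, protein, calcium). Zinc co-varies strongly with total
#: food intake (protein) and with phytate-bearing staples; the rest is a
#: weak common "eats more of everything" factor. An assumption, not a
#: survey estimate.
DEFAULT_RANK_CORRELATION = np.array(
    [
        [1.0, 0.5, 0.5, 0.3],
        [0.5, 1.0, 0.3, 0.3],
        [0.5, 0.3, 1.0, 0.3],
        [0.3, 0.3, 0.3, 1.0],
    ]
)

_BAND_RANGES = {
    AgeBand.Y19_30: (19, 30),
    AgeBand.Y31_50: (31, 50),
    AgeBand.Y51_70: (51, 70),
}


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Fit (location, scale) of a lognormal to printed quartiles.

    The location reproduces the median exactly; the scale reproduces
    the quartile ratio Q3/Q1. A degenerate spread (q1 == q3) yields
    scale 0, a point mass at the median.
    """
    if not 0 < q1 <= median <= q3:
        raise ValueError(
            f"need 0 < Q1 <= median <= Q3, got ({q1}, {median}, {q3})"
        )
    return float(np.log(median)), float(np.log(q3 / q1) / (2.0 * Z75))


@dataclass(frozen=True)
class StratumGeneratorConfig:
    """Marginals and joint structure for one stratum's draws."""

    stratum: StratumKey
    n: int
    #: nutrient -> (median, q1, q3) targets in reporting units.
    targets: Mapping[str, tuple[float, float, float]]
    rank_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_RANK_CORRELATION.copy()
    )

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"stratum size must be positive, got {self.n}")
        missing = set(NUTRIENT_COLUMNS) - set(self.targets)
        if missing:
            raise ValueError(f"targets missing nutrient(s): {sorted(missing)}")
        corr = np.asarray(self.rank_correlation, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValueError("rank correlation must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("rank correlation must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("rank correlation matrix is not positive semi-definite")

    def marginals(self) -> dict[str, tuple[float, float]]:
        return {
            nutrient: lognormal_from_quartiles(*self.targets[nutrient])
            for nutrient in NUTRIENT_COLUMNS
        }


def default_configs(
    n_override: int | None = None,
    rank_correlation: np.ndarray | None = None,
) -> list[StratumGeneratorConfig]:
    """One config per stratum with the published survey targets.

    ``n_override`` replaces every stratum size (e.g. 500 for a quick
    run, 10**5 for calibration studies); the default sizes are the
    published stratum counts.
    """
    corr = DEFAULT_RANK_CORRELATION if rank_correlation is None else rank_correlation
    configs = []
    for stratum, spec in ensin2005.INTAKE_TARGETS.items():
        targets = {nutrient: spec[nutrient] for nutrient in NUTRIENT_COLUMNS}
        configs.append(
            StratumGeneratorConfig(
                stratum=stratum,
                n=n_override or spec["n"],
                targets=targets,
                rank_correlation=corr,
            )
        )
    return configs


def _stratum_rng(master_seed: int, stratum: StratumKey) -> np.random.Generator:
    """Independent, stable stream per stratum derived from the master seed."""
    tag = zlib.crc32(stratum.label().encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def _generate_stratum(config: StratumGeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    # Gaussian copula: Spearman rho on the lognormal scale equals
    # Spearman rho of the underlying normals, which maps to a Pearson
    # correlation of 2*sin(pi*rho/6).
    pearson = 2.0 * np.sin(np.pi * np.asarray(config.rank_correlation) / 6.0)
    np.fill_diagonal(pearson, 1.0)
    # Tiny ridge guards the Cholesky factorisation at rho = +/-1 corners.
    chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(4))
    z = rng.standard_normal((config.n, 4)) @ chol.T
    marginals = config.marginals()
    data = {}
    for j, nutrient in enumerate(NUTRIENT_COLUMNS):
        mu, sigma = marginals[nutrient]
        data[nutrient] = np.exp(mu + sigma * z[:, j])
    lo, hi = _BAND_RANGES[config.stratum.age_band]
    sex_code = "m" if config.stratum.sex is Sex.MALE else "f"
    band_code = config.stratum.age_band.value.replace("-", "")
    frame = pd.DataFrame(
        {
            "id": [f"{sex_code}{band_code}-{i:06d}" for i in range(config.n)],
            "sex": config.stratum.sex.value,
            "age_years": rng.integers(lo, hi + 1, size=config.n),
            **data,
        }
    )
    return frame


def generate_cohort(
    configs: Sequence[StratumGeneratorConfig], seed: int
) -> pd.DataFrame:
    """Draw a full synthetic cohort, deterministic in (configs, seed)."""
    frames = [
        _generate_stratum(config, _stratum_rng(seed, config.stratum))
        for config in configs
    ]
    cohort = pd.concat(frames, ignore_index=True)
    if cohort["id"].duplicated().any():
        raise ValueError("duplicate record ids across strata")
    return cohort


def calibration_report(
    cohort: pd.DataFrame,
    targets: Mapping[StratumKey, Mapping] = ensin2005.INTAKE_TARGETS,
    tol: float = 0.02,
    quartile_tol: float | None = None,
) -> pd.DataFrame:
    """Relative error of sample quartiles against published targets.

    One row per stratum × nutrient with the sample median/Q1/Q3, the
    targets, relative errors, and pass flags at ``tol`` for the median
    and ``quartile_tol`` (defaults to ``tol``) for Q1/Q3 — quartiles of
    the symmetric-in-log fit deviate from asymmetric printed pairs, so
    callers typically pass a looser quartile tolerance.
    """
    if cohort.empty:
        raise ValueError("cannot calibrate an empty cohort")
    if quartile_tol is None:
        quartile_tol = tol
    if "age_band" not in cohort.columns:
        from .intake import add_derived_columns

        cohort = add_derived_columns(cohort)
    rows = []
    for stratum, spec in targets.items():
        mask = (cohort["sex"] == stratum.sex.value) & (
            cohort["age_band"] == stratum.age_band.value
        )
        if not mask.any():
            raise ValueError(f"cohort has no records in stratum {stratum.label()}")
        sub = cohort.loc[mask]
        for nutrient in NUTRIENT_COLUMNS:
            t_med, t_q1, t_q3 = spec[nutrient]
            q1, med, q3 = tukey_hinges(sub[nutrient])
            rel = lambda sample, target: abs(sample - target) / target
            rows.append(
                {
                    "stratum": stratum.label(),
                    "nutrient": nutrient,
                    "n": int(mask.sum()),
                    "median": med, "q1": q1, "q3": q3,
                    "target_median": t_med, "target_q1": t_q1, "target_q3": t_q3,
                    "rel_err_median": rel(med, t_med),
                    "rel_err_q1": rel(q1, t_q1),
                    "rel_err_q3": rel(q3, t_q3),
                    "pass_median": rel(med, t_med) <= tol,
                    "pass_q1": rel(q1, t_q1) <= quartile_tol,
                    "pass_q3": rel(q3, t_q3) <= quartile_tol,
                }
            )
    return pd.DataFrame(rows)
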