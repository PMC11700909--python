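"""Saturable zinc absorption: total (TAZ) and fractional (FAZ) absorbed zinc.

The model treats intestinal zinc uptake as an equilibrium between zinc,
a saturable absorptive pathway (transporter "receptor" sites) and
luminal phytate, which chelates zinc and removes it from the absorbable
pool. At steady state the total absorbed zinc TAZ (mmol/day) is the
physically admissible root of a quadratic in daily zinc intake TDZ:

    B   = a_max + TDZ + k_r * (1 + TDP / k_p)
    TAZ = (B - sqrt(B**2 - 4 * a_max * TDZ)) / 2

with TDP the daily phytate intake (mmol/day) and parameters

* ``a_max`` — maximal absorbable zinc per day (plateau), mmol/day;
* ``k_r``  — zinc–receptor dissociation-scale constant, mmol/day;
* ``k_p``  — zinc–phytate binding-scale constant, mmol/day.

Fractional absorption FAZ = TAZ / TDZ decreases with zinc intake
(diminishing fractional absorption) and with phytate. In trivariate
mode the parameters are additionally adjusted per individual from daily
protein (which raises the absorptive ceiling) and calcium (which
deepens phytate binding through co-precipitation); the adjustment is a
configurable log-linear map whose directions are validated on a probe
grid so that calcium can never raise, nor protein lower, FAZ.

All public cohort-level entry points take mg/day (the reporting unit)
and convert to mmol/day internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intake import (
    CALCIUM_MOLAR_MASS,
    IntakeRecord,
    MolarConstants,
    to_millimoles,
)

#: Recognised covariate-adjustment coefficients (per-unit log-scale slopes).
COEFFICIENT_KEYS = ("log_a_max_per_g_protein", "log_k_p_per_mmol_calcium")


@dataclass(frozen=True)
class ModelParams:
    """Saturable-model parameters, all in mmol/day."""

    a_max: float
    k_r: float
    k_p: float

    def __post_init__(self) -> None:
        for name in ("a_max", "k_r", "k_p"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {value}")


@dataclass(frozen=True)
class CovariateSpec:
    """How daily protein (g) and calcium (mmol) adjust the model parameters.

    ``bivariate`` mode is the identity (zinc and phytate only).
    ``trivariate`` mode applies per-individual multipliers::

        a_max_i = a_max * exp(c_protein * TDPr_i)
        k_p_i   = k_p   * exp(c_calcium * TDC_i)

    with ``c_protein = coefficients["log_a_max_per_g_protein"] >= 0``
    and ``c_calcium = coefficients["log_k_p_per_mmol_calcium"] <= 0``
    so the adjustment can only act in the physiological direction.
    """

    mode: str = "bivariate"
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("bivariate", "trivariate"):
            raise ValueError(f"unknown covariate mode: {self.mode!r}")
        unknown = set(self.coefficients) - set(COEFFICIENT_KEYS)
        if unknown:
            raise ValueError(f"unknown covariate coefficient(s): {sorted(unknown)}")

    @property
    def protein_slope(self) -> float:
        return float(self.coefficients.get("log_a_max_per_g_protein", 0.0))

    @property
    def calcium_slope(self) -> float:
        return float(self.coefficients.get("log_k_p_per_mmol_calcium", 0.0))


@dataclass(frozen=True)
class AbsorptionResult:
    """Per-individual absorption: TAZ in mg/day and FAZ as a fraction."""

    taz_mg: float
    faz: float


def _taz_arrays(tdz, tdp, a_max, k_r, k_p):
    """Closed-form lower root of the equilibrium quadratic (broadcasting)."""
    tdz = np.asarray(tdz, dtype=float)
    tdp = np.asarray(tdp, dtype=float)
    b = a_max + tdz + k_r * (1.0 + tdp / k_p)
    disc = b * b - 4.0 * a_max * tdz
    if np.any(disc < 0):
        # Analytically impossible for positive parameters; a negative
        # discriminant means a broken configuration, so fail loudly.
        raise ValueError("negative discriminant in absorption quadratic; check model config")
    return 0.5 * (b - np.sqrt(disc))


def taz_closed_form(tdz: float, tdp: float, params: ModelParams):
    """Total absorbed zinc (mmol/day) for intakes in mmol/day.

    Accepts scalars or arrays; the result satisfies
    ``0 <= TAZ <= min(a_max, tdz)`` for all valid inputs.
    """
    if np.any(np.asarray(tdz) < 0) or np.any(np.asarray(tdp) < 0):
        raise ValueError("zinc and phytate intakes must be non-negative")
    result = _taz_arrays(tdz, tdp, params.a_max, params.k_r, params.k_p)
    if not np.all(np.isfinite(result)):
        raise ValueError("non-finite absorption result")
    return float(result) if np.ndim(result) == 0 else result


def faz(tdz: float, tdp: float, params: ModelParams):
    """Fractional absorbed zinc, TAZ/TDZ, in (0, 1).

    At zero zinc intake the ratio is taken as its analytic limit
    ``a_max / (a_max + k_r * (1 + tdp/k_p))`` so cohort summaries are
    total functions.
    """
    tdz_arr = np.asarray(tdz, dtype=float)
    tdp_arr = np.asarray(tdp, dtype=float)
    taz = taz_closed_form(tdz_arr, tdp_arr, params)
    limit = params.a_max / (params.a_max + params.k_r * (1.0 + tdp_arr / params.k_p))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tdz_arr > 0, np.divide(taz, np.where(tdz_arr > 0, tdz_arr, 1.0)), limit)
    return float(ratio) if np.ndim(ratio) == 0 else ratio


def effective_params(
    tdpr: float, tdc: float, base: ModelParams, spec: CovariateSpec
) -> ModelParams:
    """Per-individual parameters after covariate adjustment.

    ``tdpr`` is daily protein in g, ``tdc`` daily calcium in mmol.
    Bivariate mode returns ``base`` unchanged.
    """
    if tdpr < 0 or tdc < 0:
        raise ValueError("covariates must be non-negative")
    if spec.mode == "bivariate":
        return base
    return ModelParams(
        a_max=base.a_max * math.exp(spec.protein_slope * tdpr),
        k_r=base.k_r,
        k_p=base.k_p * math.exp(spec.calcium_slope * tdc),
    )


def validate_covariate_spec(
    spec: CovariateSpec,
    base: ModelParams,
    protein_range: tuple[float, float] = (0.0, 300.0),
    calcium_range: tuple[float, float] = (0.0, 125.0),
    n_probe: int = 9,
) -> None:
    """Check the adjustment's direction and positivity on a probe grid.

    Over the grid, FAZ must be non-increasing in calcium and
    non-decreasing in protein (holding all else fixed), and every
    adjusted parameter set must remain strictly positive. Raises
    ``ValueError`` on violation; called when a model config is loaded.
    """
    if spec.mode == "bivariate":
        return
    proteins = np.linspace(*protein_range, n_probe)
    calciums = np.linspace(*calcium_range, n_probe)
    probe_tdz, probe_tdp = 0.12, 0.9  # typical adult intakes, mmol/day
    for tdc in calciums:
        values = [
            faz(probe_tdz, probe_tdp, effective_params(p, tdc, base, spec))
            for p in proteins
        ]
        if np.any(np.diff(values) < -1e-12):
            raise ValueError("covariate spec lets higher protein decrease FAZ")
    for tdpr in proteins:
        values = [
            faz(probe_tdz, probe_tdp, effective_params(tdpr, c, base, spec))
            for c in calciums
        ]
        if np.any(np.diff(values) > 1e-12):
            raise ValueError("covariate spec lets higher calcium increase FAZ")


def absorb_frame(
    df: pd.DataFrame,
    base: ModelParams,
    spec: CovariateSpec = CovariateSpec(),
    constants: MolarConstants = MolarConstants(),
) -> pd.DataFrame:
    """Vectorised cohort absorption; returns a copy with ``taz_mg``/``faz``.

    Expects the internal cohort columns ``zinc_mg``, ``phytate_mg``,
    ``protein_g``, ``calcium_mg``.
    """
    out = df.copy()
    tdz = to_millimoles(out["zinc_mg"].to_numpy(dtype=float), constants.zinc_molar_mass)
    tdp = to_millimoles(out["phytate_mg"].to_numpy(dtype=float), constants.phytate_molar_mass)
    if spec.mode == "trivariate":
        tdpr = out["protein_g"].to_numpy(dtype=float)
        tdc = to_millimoles(out["calcium_mg"].to_numpy(dtype=float), CALCIUM_MOLAR_MASS)
        a_max = base.a_max * np.exp(spec.protein_slope * tdpr)
        k_p = base.k_p * np.exp(spec.calcium_slope * tdc)
    else:
        a_max = np.full(len(out), base.a_max)
        k_p = np.full(len(out), base.k_p)
    if np.any(a_max <= 0) or np.any(k_p <= 0):
        raise ValueError("covariate adjustment produced non-positive parameters")
    taz = _taz_arrays(tdz, tdp, a_max, base.k_r, k_p)
    limit = a_max / (a_max + base.k_r * (1.0 + tdp / k_p))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tdz > 0, taz / np.where(tdz > 0, tdz, 1.0), limit)
    out["taz_mg"] = taz * constants.zinc_molar_mass
    out["faz"] = frac
    return out


def absorb_record(
    record: IntakeRecord,
    base: ModelParams,
    spec: CovariateSpec = CovariateSpec(),
    constants: MolarConstants = MolarConstants(),
) -> AbsorptionResult:
    """Scalar composition of the pipeline steps for one individual."""
    tdz = to_millimoles(record.zinc_mg, constants.zinc_molar_mass)
    tdp = to_millimoles(record.phytate_mg, constants.phytate_molar_mass)
    tdc = to_millimoles(record.calcium_mg, CALCIUM_MOLAR_MASS)
    params = effective_params(record.protein_g, tdc, base, spec)
    taz = taz_closed_form(tdz, tdp, params)
    return AbsorptionResult(
        taz_mg=taz * constants.zinc_molar_mass,
        faz=faz(tdz, tdp, params),
    )


def absorb_cohort(
    records: Sequence[IntakeRecord],
    base: ModelParams,
    spec: CovariateSpec = CovariateSpec(),
    constants: MolarConstants = MolarConstants(),
) -> list[AbsorptionResult]:
    """Apply the model to every record, aligned 1:1 with the input."""
    results = []
    for record in records:
        try:
            results.append(absorb_record(record, base, spec, constants))
        except ValueError as exc:
            raise ValueError(f"record {record.id!r}: {exc}") from exc
    return results
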