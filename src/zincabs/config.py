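"""YAML/JSON configuration for model parameters, standards and generation.

Three config kinds, all plain mappings (YAML is a superset of JSON, so
either syntax loads):

* model config — ``{mode, a_max, k_r, k_p, coefficients, provenance}``
  in mmol/day, validated into (:class:`~zincabs.absorption.ModelParams`,
  :class:`~zincabs.absorption.CovariateSpec`) with the covariate
  direction probe run at load time;
* standards config — mirrors
  :class:`~zincabs.dri.ReferenceStandards` field for field;
* generator config — per-stratum sizes, quartile targets and a rank
  correlation matrix for :mod:`zincabs.synthetic`.

Packaged defaults live under ``zincabs/data/`` and are addressed by
name, e.g. ``packaged_path("model_reference.yaml")``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .absorption import CovariateSpec, ModelParams, validate_covariate_spec
from .dri import ReferenceStandards
from .intake import AgeBand, Sex, StratumKey
from .synthetic import DEFAULT_RANK_CORRELATION, StratumGeneratorConfig

PACKAGED_CONFIGS = (
    "model_reference.yaml",
    "model_test.yaml",
    "model_trivariate_synthetic.yaml",
    "standards_iom_colombia.yaml",
)


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged default config."""
    path = resources.files("zincabs").joinpath("data", name)
    with resources.as_file(path) as concrete:
        return Path(concrete)


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return data


def load_model_config(path: str | Path) -> tuple[ModelParams, CovariateSpec]:
    """Load and validate a model config (runs the direction probe)."""
    data = _load_mapping(path)
    for key in ("a_max", "k_r", "k_p"):
        if key not in data:
            raise ValueError(f"model config {path} missing {key!r}")
    params = ModelParams(
        a_max=float(data["a_max"]), k_r=float(data["k_r"]), k_p=float(data["k_p"])
    )
    spec = CovariateSpec(
        mode=data.get("mode", "bivariate"),
        coefficients={k: float(v) for k, v in (data.get("coefficients") or {}).items()},
    )
    validate_covariate_spec(spec, params)
    return params, spec


def load_standards_config(path: str | Path) -> ReferenceStandards:
    data = _load_mapping(path)
    data.pop("provenance", None)
    return ReferenceStandards(**{k: float(v) for k, v in data.items()})


def load_generator_config(path: str | Path) -> list[StratumGeneratorConfig]:
    """Load per-stratum generator configs.

    Schema::

        rank_correlation: [[...4x4...]]   # optional
        strata:
          - sex: male
            age_band: "19-30"
            n: 2754
            targets:
              zinc_mg: [8.1, 5.5, 11.4]   # median, q1, q3
              ...
    """
    data = _load_mapping(path)
    corr = np.asarray(data.get("rank_correlation", DEFAULT_RANK_CORRELATION), dtype=float)
    strata = data.get("strata")
    if not strata:
        raise ValueError(f"generator config {path} has no strata")
    configs = []
    for entry in strata:
        stratum = StratumKey(Sex.parse(entry["sex"]), AgeBand(entry["age_band"]))
        targets = {
            nutrient: tuple(float(x) for x in triple)
            for nutrient, triple in entry["targets"].items()
        }
        configs.append(
            StratumGeneratorConfig(
                stratum=stratum,
                n=int(entry["n"]),
                targets=targets,
                rank_correlation=corr,
            )
        )
    return configs
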