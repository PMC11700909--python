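import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from zincabs import CovariateSpec, ModelParams
from zincabs.config import load_model_config, packaged_path


@pytest.fixture(scope="session")
def unit_params() -> ModelParams:
    """Unit model parameters (a_max = k_r = k_p = 1 mmol/day)."""
    params, _ = load_model_config(packaged_path("model_test.yaml"))
    return params


@pytest.fixture(scope="session")
def reference_model() -> tuple[ModelParams, CovariateSpec]:
    return load_model_config(packaged_path("model_reference.yaml"))


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    """Four hand-placed adults straddling the female EAR/RDA cutoffs."""
    return pd.DataFrame(
        {
            "id": ["a", "b", "c", "d"],
            "sex": ["female"] * 4,
            "age_years": [25, 28, 40, 60],
            "zinc_mg": [5.0, 6.9, 7.5, 9.0],
            "phytate_mg": [400.0, 500.0, 450.0, 600.0],
            "protein_g": [45.0, 50.0, 40.0, 35.0],
            "calcium_mg": [280.0, 300.0, 250.0, 230.0],
        }
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240513)
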