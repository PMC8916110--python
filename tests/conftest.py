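import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fcaging import GeneratorConfig, generate_cohort, generate_connectomes

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A compact cohort with a clearly detectable planted subnetwork."""
    return GeneratorConfig(
        n_subjects=150,
        n_rois=40,
        seed=42,
        planted_slope=-0.005,
        planted_edge_fraction=0.3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_stack(small_config, small_cohort):
    stack, truth = generate_connectomes(small_config, small_cohort)
    return stack, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
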