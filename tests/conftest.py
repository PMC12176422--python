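import numpy as np
import pytest

from tauspread.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A cohort small enough for fast end-to-end runs."""
    return SimulationConfig(
        grid_shape=(10, 10, 10),
        n_young_controls=15,
        n_per_stage={"OC": 40, "Preclinical": 20, "Symptomatic": 10},
        visits_per_subject=3,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
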