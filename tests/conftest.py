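import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromalink.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast configuration exercising every layer of the generator."""
    return SimConfig(
        n_loops=2_000,
        n_genes=1_000,
        n_de_genes=60,
        n_background_peaks=400,
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
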