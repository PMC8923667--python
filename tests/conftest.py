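import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import inttopo as it

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> it.SyntheticConfig:
    """Desk-scale stated world: 6 regions x 20 voxels, 700 TRs, 5 runs."""
    return it.SyntheticConfig(n_subjects=2, n_runs=3, n_timepoints=700, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> it.SyntheticDataset:
    return it.generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
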