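import numpy as np
import pytest

from wmhnet import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small effect-configured cohort shared by slower tests."""
    config = CohortConfig(
        n_per_group={"HC": 6, "WMH-no-CI": 6, "WMH-CI": 6},
        n_nodes=40, edge_attenuation=0.5, seed=7)
    records, connectomes = generate_cohort(config)
    return config, records, connectomes
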