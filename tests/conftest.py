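import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from conncog.synthcohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A quick cohort with a strong planted effect at four nodes."""
    return SimulationConfig(
        n_hv=12, n_cp=14, n_ci=14, n_nodes=16,
        edge_presence_prob=0.7,
        delta_cp=0.12, delta_ci=0.18,
        vulnerable_nodes=(0, 1, 2, 3),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20241007)
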