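import numpy as np
import pytest

from xoinfer.core import HSParameters
from xoinfer.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def trio_population():
    """Small error-free trio population with truth tracks (1 chromosome)."""
    cfg = SimulationConfig(
        n_parents=30,
        n_offspring=6,
        chrom_lengths={"1": 1.0},
        nu0=10.0,
        p0=0.05,
        markers_per_chromosome=150,
        error_rate=0.0,
        seed=424,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def default_params():
    return HSParameters(10.0, 0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
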