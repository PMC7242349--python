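import numpy as np
import pytest

from gslens import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def toy_dataset():
    """Small clean-ish simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=60,
        n_chromosomes=2,
        markers_per_chromosome=25,
        n_qtl=4,
        heritability=0.5,
        outlier_fraction=0.05,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
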