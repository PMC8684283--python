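import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nfaascan.layout import GenomeLayout, WindowGrid
from nfaascan.simulate import BreedSpec, SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_layout():
    return GenomeLayout({"chr1": 10_000_000, "chr2": 5_500_000})


@pytest.fixture(scope="session")
def toy_grid(toy_layout):
    return WindowGrid(toy_layout, 1_000_000)


@pytest.fixture(scope="session")
def tiny_config():
    """A 2 x 4-Mb genome with one planted 1-Mb segment and three breeds."""
    return SimulationConfig(
        chrom_lengths={"chr1": 4_000_000, "chr2": 4_000_000},
        planted_segments=[("chr1", 1_000_000, 2_000_000)],
        breeds=[
            BreedSpec("tauA", "A", 1.0, 6),
            BreedSpec("indB", "B", 0.0, 6),
            BreedSpec("mixAB", "B", 0.5, 4),
        ],
        divergence_density=400.0,
        polymorphism_density=200.0,
        epsilon=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config, with_genotypes=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
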