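import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from mosaicmeth.simulate import SimulationConfig, build_synthetic_genome  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact genome used across module tests: 2 x 150 kb, 60 genes."""
    return SimulationConfig(
        seed=13,
        n_contigs=2,
        contig_length=150_000,
        n_genes=60,
        n_convergent_shared_pairs=2,
        control_contig_length=20_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return build_synthetic_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
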