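import pytest

from liquidcnv import (
    default_genome,
    default_rules,
    simulate_reference_pool,
    uniform_bins,
)


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def bins200(genome):
    """Uniform characterization panel: 200 bins on every modeled arm."""
    return uniform_bins(genome, 200)


@pytest.fixture(scope="session")
def reference200(bins200):
    return simulate_reference_pool(bins200, n_normals=20, mean_depth=500,
                                   noise_sigma=0.15, seed=7)


@pytest.fixture(scope="session")
def bins40(genome):
    """Small uniform panel for cheap end-to-end checks."""
    return uniform_bins(genome, 40)


@pytest.fixture(scope="session")
def reference40(bins40):
    return simulate_reference_pool(bins40, n_normals=20, mean_depth=500,
                                   noise_sigma=0.15, seed=7)
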