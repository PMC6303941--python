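import numpy as np
import pytest

from strandmeth import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """Counts-level synthetic dataset, 2000 bins (fast, shared)."""
    return simulate_dataset(SimulationConfig(n_bins=2000, seed=7))


@pytest.fixture(scope="session")
def reads_sim(tmp_path_factory):
    """Read-level synthetic dataset (FASTA + SAM + truth tables)."""
    out = tmp_path_factory.mktemp("simreads")
    cfg = SimulationConfig(n_bins=300, seed=11)
    data = simulate_dataset(cfg, emit="reads", out_dir=str(out))
    return data, out
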