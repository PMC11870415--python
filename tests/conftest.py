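import numpy as np
import pytest

from clonmem.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """Two samples, small matrices — fast end-to-end runs."""
    return SimulationConfig(
        seed=11, n_samples=2, conditions=("control", "colitis"),
        n_cells_per_sample=100, n_clones_per_sample=10,
        n_peaks=400, n_genes=200, n_families=4,
        umis_per_cell=10, reads_per_umi=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
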