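import numpy as np
import pytest

from popinfer import CellMatrix, CellOrdering, RunConfig, SimConfig, simulate


@pytest.fixture
def small_expr():
    """3 genes x 4 cells expression matrix with known values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.0, 1.0, 0.0, 1.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )
    return CellMatrix(values, ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def small_ordering():
    return CellOrdering.from_pseudotime(
        ["c1", "c2", "c3", "c4"], [0.3, 0.1, 0.9, 0.5]
    )


@pytest.fixture(scope="session")
def sim_noise_free():
    """Noise-free synthetic multiome dataset (fixed seed)."""
    return simulate(SimConfig(noise_sd=0.0, dropout_rate=0.0, n_cells=600, seed=0))


@pytest.fixture(scope="session")
def sim_noisy():
    """Default (moderate-noise) synthetic multiome dataset."""
    return simulate(SimConfig(n_cells=600, seed=0))


@pytest.fixture(scope="session")
def fast_config():
    """Inference config scaled for unit tests (coarse alpha grid)."""
    return RunConfig(n_pseudocells=30, alpha_step=0.01)
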