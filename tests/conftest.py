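import numpy as np
import pytest

from tilokit import synthio


@pytest.fixture(scope="session")
def study_sim():
    """One simulated chromosome under the default study conditions."""
    params = synthio.study_params(seed=0)
    cmap, truth = synthio.simulate_chromosome(params)
    return cmap, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast chromosome: 8 TADs x 6 bins, 2 planted clusters."""
    params = synthio.study_params(
        n_tads=8, tad_bins=6, n_clusters=2, depth=2e5, seed=7
    )
    cmap, truth = synthio.simulate_chromosome(params)
    return cmap, truth


def random_network(n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.random((n, n))
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return w
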