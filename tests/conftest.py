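import numpy as np
import pytest

from spatialmux import TissueSpec, simulate_tissue
from spatialmux.synthetic_tissue import _latent_and_spatial_graphs


@pytest.fixture(scope="session")
def small_tissue():
    """A desk-scale noisy four-layer tissue shared across tests."""
    spec = TissueSpec(n_spots=400, n_genes=200, noise_mixing=0.2, seed=7)
    coords, truth, X = simulate_tissue(spec)
    return spec, coords, truth, X


@pytest.fixture(scope="session")
def small_graphs(small_tissue):
    _, coords, _, X = small_tissue
    latent_g, spatial_g = _latent_and_spatial_graphs(X, coords)
    return latent_g, spatial_g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
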