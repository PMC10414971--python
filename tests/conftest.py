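import numpy as np
import pytest

from gradplast.synthetic import LatentManifold, make_connectome


@pytest.fixture(scope="session")
def small_connectome():
    """60-parcel latent-manifold connectome with its generating coordinates."""
    manifold = LatentManifold.random(60, seed=11, kernel_scale=1.0, noise_sd=0.01)
    return make_connectome(manifold, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
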