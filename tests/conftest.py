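import numpy as np
import pytest

from trioseg import BrainMask, default_brainweb_like_spec, render_phantom
from trioseg.phantom import default_seeds


@pytest.fixture(scope="session")
def small_phantom():
    """32-cubed, 1% noise phantom shared by the fast unit tests."""
    spec = default_brainweb_like_spec(1, 0, rng_seed=42, grid_shape=(32, 32, 32))
    return render_phantom(spec)


@pytest.fixture(scope="session")
def small_seeds(small_phantom):
    return default_seeds(small_phantom.spec)


@pytest.fixture(scope="session")
def full_mask(small_phantom):
    return BrainMask(np.ones(small_phantom.truth.grid_shape, dtype=bool))
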