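import numpy as np
import pytest

from conntarget import default_grid, default_masks


@pytest.fixture(scope="session")
def small_masks():
    """Seed/parietal/brain masks on a 28x32x28 grid at 2 mm."""
    return default_masks((28, 32, 28))


@pytest.fixture(scope="session")
def small_grid():
    return default_grid((28, 32, 28))


@pytest.fixture(scope="session")
def grid12():
    return default_grid((12, 12, 12))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
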