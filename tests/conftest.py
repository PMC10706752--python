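import numpy as np
import pytest

from abisa.synthetic import SyntheticTileSpec, make_tile


@pytest.fixture(scope="session")
def white_tile():
    return make_tile(SyntheticTileSpec("white", size_px=128, seed=5))


@pytest.fixture(scope="session")
def texture_tile():
    return make_tile(SyntheticTileSpec("non_recurring", size_px=128, seed=5))


@pytest.fixture(scope="session")
def band_tile():
    return make_tile(SyntheticTileSpec("recurring", size_px=128, seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
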