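import numpy as np
import pytest

from scstain import phantom as ph


@pytest.fixture(scope="session")
def phantom_slice():
    return ph.make_cortex_phantom(128, 128, seed=0)


@pytest.fixture(scope="session")
def noise_free_slice():
    params = ph.PhantomParams(speckle_var=0.0)
    return ph.make_cortex_phantom(128, 128, seed=0, params=params)


@pytest.fixture(scope="session")
def weak_pair(phantom_slice):
    return ph.make_weak_pair(phantom_slice, amplitude=8.0, content_jitter=0.0,
                             seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
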