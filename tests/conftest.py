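import numpy as np
import pytest

from immunotme import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_region():
    """One rendered synthetic region reused by imaging tests."""
    spec, pops = syn.tme_scenario(seed=7)
    image, cells = syn.generate_region(spec, pops, render=True)
    return spec, pops, image, cells
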