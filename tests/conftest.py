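import numpy as np
import pytest

from shapenum import montage as montage_mod


@pytest.fixture(scope="session")
def montage():
    return montage_mod.make_montage()


@pytest.fixture(scope="session")
def ground_truth(montage):
    return montage_mod.make_ground_truth(1, montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
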