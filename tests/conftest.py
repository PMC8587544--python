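import numpy as np
import pytest

from vscreen.synthetic import (
    make_fingerprint_dataset,
    make_motif_library,
    make_pharmacophore_set,
)


@pytest.fixture(scope="session")
def fingerprint_dataset():
    return make_fingerprint_dataset(1000, seed=1)


@pytest.fixture(scope="session")
def motif_library():
    return make_motif_library(400, seed=2)


@pytest.fixture(scope="session")
def pharmacophore_set():
    return make_pharmacophore_set(5, 10, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
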