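import numpy as np
import pytest

from sigarch.catalogue_io import SignatureMatrix
from sigarch.contexts import N_CONTEXTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def onehot_signatures():
    """Three mutually orthogonal one-hot profiles."""
    rows = np.zeros((3, N_CONTEXTS))
    rows[0, 0] = rows[1, 40] = rows[2, 95] = 1.0
    return SignatureMatrix(["H1", "H2", "H3"], rows)


@pytest.fixture
def random_signatures(rng):
    """Five random nonnegative normalised profiles."""
    raw = rng.uniform(size=(5, N_CONTEXTS)) ** 3
    return SignatureMatrix.from_profiles([f"R{i}" for i in range(5)], raw)
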