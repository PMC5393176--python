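import numpy as np
import pytest

from rnassess import build_duplex


def norm_pairs(pairs):
    """Unordered residue-key pairs as a canonical set."""
    return {tuple(sorted(p)) for p in pairs}


def random_rotation(rng):
    """Uniform proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def duplex8():
    return build_duplex("GGGGCCCC")


@pytest.fixture
def duplex12():
    return build_duplex("GACUGGCUAGCU")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
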