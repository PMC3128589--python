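import numpy as np
import pytest

from caterpillar.energy import ModelParameters
from caterpillar.fixtures import make_compact_toy, make_extended, make_ideal_helix
from caterpillar.geometry import build_backbone


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def helix16():
    return make_ideal_helix(16)


@pytest.fixture(scope="session")
def extended16():
    return make_extended(16)


@pytest.fixture(scope="session")
def compact16():
    return make_compact_toy(16, seed=3)


def random_chain(n, rng, spread=np.pi):
    """Random-torsion chain (may self-overlap; fine for geometry tests)."""
    t = rng.uniform(-spread, spread, size=(n, 2))
    return build_backbone(t)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
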