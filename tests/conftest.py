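import numpy as np
import pytest

from rcus.volumes import LatticeSpec, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_lattice():
    return LatticeSpec((8, 4, 8), (0.5, 0.5, 0.5), (-2.0, -1.0, 1.0))


@pytest.fixture
def slice_lattice():
    """Single-slice (ny = 1) lattice used by the MCRF tests."""
    return LatticeSpec((16, 1, 16), (0.25, 0.25, 0.25), (-2.0, 0.0, 2.0))


def make_volume(lattice, values, domain="linear"):
    return Volume3D(lattice, np.asarray(values, dtype=float), domain)
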