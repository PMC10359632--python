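import numpy as np
import pytest

from rotascan import fixtures as fx
from rotascan.forcefield import default_parameters


@pytest.fixture(scope="session")
def ff():
    return default_parameters()


@pytest.fixture(scope="session")
def helix10():
    """Mixed 10-residue alpha helix used by scanner and evaluation tests."""
    return fx.build_helix(
        ["ALA", "SER", "LEU", "VAL", "THR", "CYS", "ASP", "ALA", "MET", "ALA"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20230713)


def wrap_diff(a: float, b: float) -> float:
    """Shortest circular difference a - b in degrees."""
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d
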