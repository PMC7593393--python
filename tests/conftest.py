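import numpy as np
import pytest

from toposep.montage import Montage, standard_montage
from toposep.synth import reduced_montage


@pytest.fixture(scope="session")
def montage64() -> Montage:
    return standard_montage()


@pytest.fixture(scope="session")
def montage20() -> Montage:
    return reduced_montage(20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_montage() -> Montage:
    """Four-channel toy montage for hand-traceable cases."""
    return Montage(("Cz", "Fz", "Pz", "C3"),
                   theta=np.array([0.0, 45.0, 45.0, 45.0]),
                   phi=np.array([0.0, 90.0, -90.0, 180.0]))
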