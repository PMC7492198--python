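import numpy as np
import pytest

from innerear import (
    BoneWave,
    CochlearGeometry,
    FluidProperties,
    InnerEarModel,
    build_sections,
)
from innerear.constants import load_model_constants


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def constants():
    return load_model_constants()


@pytest.fixture(scope="session")
def geom(constants):
    return CochlearGeometry.from_constants(constants)


@pytest.fixture(scope="session")
def sections(geom):
    return build_sections(geom)


@pytest.fixture(scope="session")
def wave():
    return BoneWave(acceleration=1.0, speed=300.0, direction=(1.0, 0.0))


@pytest.fixture(scope="session")
def model():
    """The full calibrated model on the packaged constants (shared; read-only)."""
    return InnerEarModel()


@pytest.fixture(scope="session")
def grid(model):
    return model.freq


def at(freq: np.ndarray, f0: float) -> int:
    """Index of an on-grid frequency."""
    i = int(np.argmin(np.abs(freq - f0)))
    assert np.isclose(freq[i], f0), f"{f0} Hz not on grid"
    return i
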