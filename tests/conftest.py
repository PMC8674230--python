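import numpy as np
import pytest

from capflex.simulate import default_calibration
from capflex.types import CapillarySystem


@pytest.fixture
def system() -> CapillarySystem:
    """Default 75 µm × 1 m capillary at 50 mbar measurement pressure."""
    return CapillarySystem()


@pytest.fixture
def fill_system() -> CapillarySystem:
    """Same capillary at the 3500 mbar fill pressure."""
    return CapillarySystem.at_pressure_mbar(3500.0)


@pytest.fixture
def calibration():
    """Clean 0.05 FU/µM standard curve through zero."""
    return default_calibration()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
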