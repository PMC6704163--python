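import numpy as np
import pytest

from octsim import FiberMode, OpticalSystem


@pytest.fixture(scope="session")
def sysm() -> OpticalSystem:
    """Default instrument: f1 = 25 mm, f2 = 36 mm, h = 3.5 mm, n_med = 1.35."""
    return OpticalSystem()


@pytest.fixture(scope="session")
def mode() -> FiberMode:
    """Default fiber mode, w0 = 4.6 um."""
    return FiberMode()


@pytest.fixture(scope="session")
def k0() -> float:
    """Vacuum wavenumber at the 1.3 um central wavelength."""
    return 2 * np.pi / 1.3e-6
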