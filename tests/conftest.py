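import numpy as np
import pytest

from silentpupil.sensitivities import load_sensitivities
from silentpupil.spectral import Spectrum, SensitivityFunction
from silentpupil.stimdesign import DeviceCalibration
from silentpupil.synthetic import make_device_calibration


@pytest.fixture(scope="session")
def sens():
    return load_sensitivities()


@pytest.fixture(scope="session")
def device():
    """Default synthetic 10-primary device (deterministic: no jitter rng)."""
    return make_device_calibration()


def boxcar(lo: float, hi: float, grid: np.ndarray) -> np.ndarray:
    return ((grid >= lo) & (grid <= hi)).astype(float)


@pytest.fixture(scope="session")
def boxcar_toy():
    """Two disjoint boxcar primaries + boxcar receptors seeing one each.

    Primary 0 emits only in the 'melanopsin' band (440–500 nm), primary 1
    only in the 'cone' band (540–600 nm); the L/M/S receptors all see only
    primary 1, melanopsin only primary 0.  Every solve on this device has a
    closed form.
    """
    grid = np.arange(380.0, 781.0, 1.0)
    p0 = Spectrum(grid, 0.01 * boxcar(440, 500, grid))
    p1 = Spectrum(grid, 0.01 * boxcar(540, 600, grid))
    zero = Spectrum(grid, np.zeros_like(grid))
    levels = ((0.0, 1.0), (0.0, 1.0))
    cal = DeviceCalibration(levels=levels, spectra=((zero, p0), (zero, p1)))

    mel_band = boxcar(440, 500, grid)
    cone_band = boxcar(540, 600, grid)
    sens_set = {
        "melanopsin": SensitivityFunction("melanopsin", grid, mel_band),
        "L": SensitivityFunction("L", grid, cone_band),
        "M": SensitivityFunction("M", grid, cone_band),
        "S": SensitivityFunction("S", grid, cone_band),
    }
    return cal, sens_set
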