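"""Photoreceptor spectral sensitivity functions.

The analysis weights spectral radiance by the relative corneal spectral
sensitivities of the five human photoreceptor classes (L-, M-, S-cone
opsins, melanopsin, rhodopsin) for a 10° field, plus the photopic
luminosity function V(λ) for conventional luminance.

The bundled table (``data/sensitivities_10deg_synthetic.csv``) is a
SYNTHETIC stand-in for the standardized alpha-opic weighting functions: it
is generated analytically from the Govardovskii et al. (2000) A1
visual-pigment template at the accepted in-situ peak wavelengths, filtered
by a smooth ocular-media (lens) density model and peak-normalized.  The
construction reproduces the qualitative structure that matters here —
heavily overlapping cone/melanopsin curves with peaks near 440/480/490/
540/565 nm — and every computation in this package uses it
self-consistently.  It is not a certified colorimetric standard.

V(λ) uses a standard single-Gaussian analytic approximation to the 2°
photopic luminosity curve, peak-normalized on the canonical grid.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .spectral import CANONICAL_GRID, SensitivityFunction

__all__ = [
    "PIGMENT_PEAKS_NM",
    "pigment_template",
    "lens_density",
    "build_sensitivity_table",
    "load_sensitivities",
    "default_sensitivities",
    "photopic_luminosity",
]

#: In-situ absorbance peak wavelengths (nm) of the A1 photopigments.
PIGMENT_PEAKS_NM = {
    "L": 558.9,
    "M": 530.3,
    "S": 420.7,
    "melanopsin": 480.0,
    "rhodopsin": 493.0,
}

_DATA_FILE = "sensitivities_10deg_synthetic.csv"


def pigment_template(wavelengths: np.ndarray, peak_nm: float) -> np.ndarray:
    """Govardovskii et al. (2000) A1 absorbance template, alpha + beta bands.

    Returns relative absorbance (unnormalized, peak ≈ 1 at ``peak_nm``).
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = peak_nm / wl
    a = 0.8795 + 0.0459 * np.exp(-((peak_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lam_beta = 189.0 + 0.315 * peak_nm
    b_beta = -40.5 + 0.195 * peak_nm
    beta = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    return alpha + beta


def lens_density(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth ocular-media optical density model (dimensionless OD).

    Monotone decreasing with wavelength: ~1.1 OD at 400 nm falling to
    ~0.02 OD in the deep red, emulating the standard-observer media
    transmission used for corneal sensitivities.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return 1.1 * np.exp((400.0 - wl) / 60.0)


def _corneal_sensitivity(wavelengths: np.ndarray, peak_nm: float) -> np.ndarray:
    pig = pigment_template(wavelengths, peak_nm)
    transmission = 10.0 ** (-lens_density(wavelengths))
    s = pig * transmission
    return s / s.max()


def _vlambda(wavelengths: np.ndarray) -> np.ndarray:
    # single-Gaussian analytic approximation to photopic V(λ)
    wl_um = np.asarray(wavelengths, dtype=float) / 1000.0
    v = 1.019 * np.exp(-285.4 * (wl_um - 0.5590) ** 2)
    return v / v.max()


def build_sensitivity_table(grid: np.ndarray | None = None) -> pd.DataFrame:
    """Recompute the bundled sensitivity table from the analytic templates."""
    if grid is None:
        grid = CANONICAL_GRID
    cols = {"wavelength": grid}
    for name, peak in PIGMENT_PEAKS_NM.items():
        cols[name] = _corneal_sensitivity(grid, peak)
    cols["V_photopic"] = _vlambda(grid)
    return pd.DataFrame(cols)


def _bundled_table() -> pd.DataFrame:
    with resources.files("silentpupil.data").joinpath(_DATA_FILE).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def load_sensitivities() -> dict[str, SensitivityFunction]:
    """Load the bundled sensitivity set, keyed by receptor name."""
    table = _bundled_table()
    wl = table["wavelength"].to_numpy(dtype=float)
    out: dict[str, SensitivityFunction] = {}
    for name in list(PIGMENT_PEAKS_NM) + ["V_photopic"]:
        vals = table[name].to_numpy(dtype=float)
        out[name] = SensitivityFunction(name, wl, np.clip(vals, 0.0, 1.0))
    return out


def default_sensitivities() -> dict[str, SensitivityFunction]:
    """Alias for :func:`load_sensitivities` (the package default set)."""
    return load_sensitivities()


def photopic_luminosity() -> SensitivityFunction:
    return load_sensitivities()["V_photopic"]
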