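"""Physiologically relevant radiometry.

Spectral radiance is weighted by photoreceptor spectral sensitivities and
integrated over wavelength to give alpha-opic radiances (W·m⁻²·sr⁻¹), from
which Weber contrasts between a stimulus pulse and its background are
computed per opsin.  Photopic luminance (cd·m⁻²) uses the luminous efficacy
constant Km = 683 lm/W.

All integration is trapezoidal on a canonical 1 nm grid spanning
380–780 nm; inputs on other grids are resampled by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CANONICAL_GRID",
    "KM_LM_PER_W",
    "Spectrum",
    "SensitivityFunction",
    "AlphaopicRadiances",
    "ContrastSet",
    "resample_spectrum",
    "alphaopic_radiance",
    "luminance",
    "weber_contrast",
    "stimulus_contrasts",
]

#: Canonical wavelength grid (nm) used for all integrations.
CANONICAL_GRID = np.arange(380.0, 781.0, 1.0)

#: Maximum luminous efficacy of photopic vision (lm/W).
KM_LM_PER_W = 683.0

RECEPTOR_NAMES = ("L", "M", "S", "melanopsin", "rhodopsin", "V_photopic")


def _as_grid(x: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """Spectral radiance on a wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelengths in nm, strictly increasing.
    values : array-like
        Spectral radiance in W·m⁻²·sr⁻¹·nm⁻¹, one value per wavelength.
    clip_negative : bool
        Clip small negative values (measurement noise) to zero on
        construction.  Default True.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    clip_negative: bool = True

    def __post_init__(self) -> None:
        wl = _as_grid(self.wavelengths, "wavelengths")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != wl.shape:
            raise ValueError("wavelengths and values must have equal length")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectral radiance values must be finite")
        if self.clip_negative:
            vals = np.clip(vals, 0.0, None)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    # Linear vector-space operations, used by the forward model and in
    # linearity property checks.
    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("spectra must share a wavelength grid to be added")
        return Spectrum(self.wavelengths, self.values + other.values,
                        clip_negative=False)

    def __mul__(self, scalar: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * float(scalar),
                        clip_negative=False)

    __rmul__ = __mul__

    def on_canonical_grid(self) -> "Spectrum":
        return resample_spectrum(self, CANONICAL_GRID)


@dataclass(frozen=True)
class SensitivityFunction:
    """Peak-normalized relative spectral sensitivity of a photoreceptor."""

    receptor_name: str
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.receptor_name not in RECEPTOR_NAMES:
            raise ValueError(
                f"receptor_name must be one of {RECEPTOR_NAMES}, "
                f"got {self.receptor_name!r}")
        wl = _as_grid(self.wavelengths, "wavelengths")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != wl.shape:
            raise ValueError("wavelengths and values must have equal length")
        if vals.min() < 0.0 or vals.max() > 1.0 + 1e-12:
            raise ValueError("sensitivity values must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class AlphaopicRadiances:
    """Receptor-weighted radiances (W·m⁻²·sr⁻¹) plus photopic luminance."""

    melanopsin: float
    L: float
    M: float
    S: float
    rhodopsin: float | None = None
    luminance_cd_m2: float = 0.0

    def as_dict(self) -> dict[str, float]:
        out = {"melanopsin": self.melanopsin, "L": self.L,
               "M": self.M, "S": self.S}
        if self.rhodopsin is not None:
            out["rhodopsin"] = self.rhodopsin
        return out


@dataclass(frozen=True)
class ContrastSet:
    """Per-opsin Weber contrast (%) of a pulse against its background."""

    melanopsin: float
    L: float
    M: float
    S: float
    rhodopsin: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"melanopsin": self.melanopsin, "L": self.L,
               "M": self.M, "S": self.S}
        if self.rhodopsin is not None:
            out["rhodopsin"] = self.rhodopsin
        return out

    @property
    def lms_mean(self) -> float:
        """Summary cone contrast: arithmetic mean of L, M and S contrasts."""
        return (self.L + self.M + self.S) / 3.0


def resample_spectrum(spectrum: Spectrum, target_grid: Iterable[float],
                      extrapolate: bool = False) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_grid``.

    Values outside the source support are zero.  With ``extrapolate=False``
    (default) a target grid extending beyond the source support is allowed —
    the spectrum is taken to be dark there — but this is made explicit so
    callers who need hard bounds can opt in to an error by passing a grid
    within support.
    """
    grid = _as_grid(np.asarray(target_grid, dtype=float), "target_grid")
    out = np.interp(grid, spectrum.wavelengths, spectrum.values,
                    left=0.0, right=0.0)
    if extrapolate:
        # hold end values instead of zeroing outside support
        out = np.interp(grid, spectrum.wavelengths, spectrum.values)
    return Spectrum(grid, out, clip_negative=False)


def _integrate_product(spectrum: Spectrum, sens: SensitivityFunction) -> float:
    lo = max(spectrum.wavelengths[0], sens.wavelengths[0])
    hi = min(spectrum.wavelengths[-1], sens.wavelengths[-1])
    if lo >= hi:
        raise ValueError(
            f"spectrum ({spectrum.wavelengths[0]:g}–{spectrum.wavelengths[-1]:g} nm) "
            f"and sensitivity {sens.receptor_name} "
            f"({sens.wavelengths[0]:g}–{sens.wavelengths[-1]:g} nm) have disjoint "
            "wavelength supports")
    # integrate over the support overlap only: a spectrum ending in a step
    # would otherwise pick up spurious half-ramp area at its edges
    grid = CANONICAL_GRID[(CANONICAL_GRID >= lo) & (CANONICAL_GRID <= hi)]
    if grid.size < 2:
        raise ValueError("support overlap too narrow to integrate")
    s = np.interp(grid, spectrum.wavelengths, spectrum.values, left=0.0, right=0.0)
    w = np.interp(grid, sens.wavelengths, sens.values, left=0.0, right=0.0)
    return float(np.trapezoid(s * w, grid))


def alphaopic_radiance(spectrum: Spectrum, sens: SensitivityFunction) -> float:
    """Alpha-opic radiance: ∫ L(λ)·s_α(λ) dλ over the canonical grid.

    Returns W·m⁻²·sr⁻¹ for a spectral radiance input in W·m⁻²·sr⁻¹·nm⁻¹.
    """
    return _integrate_product(spectrum, sens)


def luminance(spectrum: Spectrum,
              vlambda: SensitivityFunction | None = None) -> float:
    """Photopic luminance in cd·m⁻²: Km·∫ L(λ)·V(λ) dλ."""
    if vlambda is None:
        from .sensitivities import photopic_luminosity
        vlambda = photopic_luminosity()
    return KM_LM_PER_W * _integrate_product(spectrum, vlambda)


def weber_contrast(pulse_radiance: float, background_radiance: float) -> float:
    """Weber contrast in percent: 100·(pulse − background)/background."""
    if background_radiance <= 0.0:
        raise ValueError("Weber contrast requires background radiance > 0")
    return 100.0 * (pulse_radiance - background_radiance) / background_radiance


def stimulus_contrasts(background: Spectrum, pulse: Spectrum,
                       sens_set: Mapping[str, SensitivityFunction] | None = None,
                       ) -> ContrastSet:
    """Per-opsin Weber contrasts of a stimulus pair.

    ``sens_set`` maps receptor names to sensitivity functions; defaults to the
    bundled melanopsin + L/M/S (+ rhodopsin) set.  Contrast is invariant to a
    common positive rescaling of both spectra because alpha-opic radiance is
    linear in the spectrum.
    """
    if sens_set is None:
        from .sensitivities import default_sensitivities
        sens_set = default_sensitivities()
    vals: dict[str, float] = {}
    for name in ("melanopsin", "L", "M", "S", "rhodopsin"):
        sens = sens_set.get(name)
        if sens is None:
            continue
        bg = alphaopic_radiance(background, sens)
        pl = alphaopic_radiance(pulse, sens)
        vals[name] = weber_contrast(pl, bg)
    return ContrastSet(
        melanopsin=vals["melanopsin"], L=vals["L"], M=vals["M"], S=vals["S"],
        rhodopsin=vals.get("rhodopsin"))


def alphaopic_radiances(spectrum: Spectrum,
                        sens_set: Mapping[str, SensitivityFunction] | None = None,
                        ) -> AlphaopicRadiances:
    """All alpha-opic radiances of a spectrum, plus its photopic luminance."""
    if sens_set is None:
        from .sensitivities import default_sensitivities
        sens_set = default_sensitivities()
    rho = sens_set.get("rhodopsin")
    return AlphaopicRadiances(
        melanopsin=alphaopic_radiance(spectrum, sens_set["melanopsin"]),
        L=alphaopic_radiance(spectrum, sens_set["L"]),
        M=alphaopic_radiance(spectrum, sens_set["M"]),
        S=alphaopic_radiance(spectrum, sens_set["S"]),
        rhodopsin=None if rho is None else alphaopic_radiance(spectrum, rho),
        luminance_cd_m2=luminance(spectrum, sens_set.get("V_photopic")),
    )
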