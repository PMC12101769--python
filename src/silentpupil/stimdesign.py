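"""Silent-substitution stimulus design on a multi-primary light source.

Given a device calibration (measured spectral radiance of each primary
across its input range), find background/pulse setting pairs that:

* maximize Weber contrast on a target photoreceptor (e.g. melanopsin)
  while nulling contrast on the silenced receptors (L, M, S cones), or
* hit a requested summary contrast on a set of target receptors
  (the cone-directed control pair) while nulling a silenced receptor.

The search is a seeded multi-start of SciPy's SLSQP constrained local
optimizer: restarts are launched from random feasible points and from
perturbations of the incumbent, and the best verified candidate is kept,
so a fixed seed reproduces the pair exactly.  Silenced-receptor contrasts
enter the solve as equality constraints driven to zero; the user-facing
silencing tolerance (default 6% absolute) is applied at verification time
when deciding whether a candidate counts as a success.

Also provides radiance-matched narrowband pairs (two single primaries
scaled to equal unweighted total radiance), used for classic red/blue
post-illumination pupil response stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .spectral import (
    CANONICAL_GRID,
    ContrastSet,
    SensitivityFunction,
    Spectrum,
    alphaopic_radiance,
    luminance,
    stimulus_contrasts,
    weber_contrast,
)

__all__ = [
    "DeviceCalibration",
    "DeviceSettings",
    "SilentSubstitutionProblem",
    "StimulusPair",
    "VerificationReport",
    "predict_spd",
    "solve_max_contrast",
    "solve_matched_contrast",
    "verify_pair",
    "narrowband_pair",
    "gamut_is_degenerate",
    "SolverFailure",
]

CONE_NAMES = ("L", "M", "S")


class SolverFailure(RuntimeError):
    """No feasible stimulus pair found within the restart budget.

    Carries the best infeasible candidate for inspection.
    """

    def __init__(self, message: str, best_candidate: "StimulusPair | None"):
        super().__init__(message)
        self.best_candidate = best_candidate


@dataclass(frozen=True)
class DeviceCalibration:
    """Measured per-primary spectra across normalized input levels.

    ``spectra[i][j]`` is the measured spectrum of primary ``i`` at input
    level ``levels[i][j]``; levels are normalized to [0, 1] (a device's
    12-bit input range maps onto this interval) and must include 0 and the
    maximum.
    """

    levels: tuple[tuple[float, ...], ...]
    spectra: tuple[tuple[Spectrum, ...], ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.spectra):
            raise ValueError("levels and spectra must cover the same primaries")
        for i, (lv, sp) in enumerate(zip(self.levels, self.spectra)):
            if len(lv) != len(sp):
                raise ValueError(f"primary {i}: levels/spectra length mismatch")
            if len(lv) < 2:
                raise ValueError(f"primary {i}: need >=2 calibration levels")
            arr = np.asarray(lv, dtype=float)
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"primary {i}: levels must be sorted ascending")
            if arr[0] != 0.0 or arr[-1] != 1.0:
                raise ValueError(f"primary {i}: levels must include 0 and 1")
        grid = self.spectra[0][0].wavelengths
        for sp_list in self.spectra:
            for sp in sp_list:
                if not np.array_equal(sp.wavelengths, grid):
                    raise ValueError("all calibration spectra must share a grid")

    @property
    def n_primaries(self) -> int:
        return len(self.levels)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0][0].wavelengths


@dataclass(frozen=True)
class DeviceSettings:
    """Normalized intensity per primary, each in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("settings must be a 1-D vector")
        if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
            raise ValueError("settings must lie within [0, 1]")
        object.__setattr__(self, "values", np.clip(arr, 0.0, 1.0))


@dataclass(frozen=True)
class SilentSubstitutionProblem:
    """Specification of a silent-substitution solve.

    Parameters
    ----------
    target : sequence of receptor names
        Receptors whose contrast is maximized (mode ``"maximize"``) or
        driven to ``match_contrast`` (mode ``"match"``).
    silenced : sequence of receptor names
        Receptors whose contrast must stay within ``silencing_tolerance``
        (% absolute) of zero.
    mode : {"maximize", "match"}
    match_contrast : float
        Requested summary Weber contrast (%) for mode ``"match"``.
    silencing_tolerance : float
        Absolute contrast (%) accepted on silenced receptors; default 6.
    background_floor : float
        Lower bound on background settings, keeping the background radiance
        bounded away from zero so Weber contrast stays finite.
    restarts, seed, max_iter, constraint_tol : optimizer controls.
    """

    target: tuple[str, ...]
    silenced: tuple[str, ...]
    mode: str = "maximize"
    match_contrast: float | None = None
    silencing_tolerance: float = 6.0
    background_floor: float = 0.05
    restarts: int = 20
    seed: int = 0
    max_iter: int = 400
    constraint_tol: float = 1e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", tuple(self.target))
        object.__setattr__(self, "silenced", tuple(self.silenced))
        if set(self.target) & set(self.silenced):
            raise ValueError("target and silenced receptor sets must be disjoint")
        if self.mode not in ("maximize", "match"):
            raise ValueError("mode must be 'maximize' or 'match'")
        if self.mode == "match" and self.match_contrast is None:
            raise ValueError("mode='match' requires match_contrast")
        if not self.silencing_tolerance > 0:
            raise ValueError("silencing_tolerance must be > 0")


@dataclass(frozen=True)
class StimulusPair:
    """A background/pulse pair with its achieved contrasts and luminances."""

    background_settings: DeviceSettings
    pulse_settings: DeviceSettings
    background_spectrum: Spectrum
    pulse_spectrum: Spectrum
    contrasts: ContrastSet
    background_luminance: float
    pulse_luminance: float
    objective: float = np.nan
    success: bool = True


@dataclass(frozen=True)
class VerificationReport:
    """Recomputed-contrast check of a pair against its problem."""

    contrasts: ContrastSet
    silenced_ok: dict[str, bool]
    target_ok: bool
    background_luminance: float
    pulse_luminance: float

    @property
    def all_silenced_ok(self) -> bool:
        return all(self.silenced_ok.values())


def gamut_is_degenerate(cal: DeviceCalibration,
                        sens_set: Mapping[str, SensitivityFunction],
                        receptor_names: Sequence[str],
                        rtol: float = 1e-8) -> bool:
    """True when the device cannot independently steer the receptor space.

    Checks the rank of the full-output receptor-radiance matrix (one column
    per primary): duplicated or collinear primaries reduce its rank below
    ``min(n_primaries, n_receptors)``.
    """
    cols = []
    for i in range(cal.n_primaries):
        settings = np.zeros(cal.n_primaries)
        settings[i] = 1.0
        spd = predict_spd(cal, DeviceSettings(settings))
        cols.append([alphaopic_radiance(spd, sens_set[nm])
                     for nm in receptor_names])
    m = np.array(cols).T
    rank = np.linalg.matrix_rank(m, tol=rtol * max(np.abs(m).max(), 1e-300))
    return rank < min(cal.n_primaries, len(receptor_names))


def predict_spd(cal: DeviceCalibration, settings: DeviceSettings) -> Spectrum:
    """Forward model: device spectrum for a settings vector.

    Each primary's spectrum is piecewise-linearly interpolated across its
    measured levels at every wavelength; the device output is the
    superposition (sum) of the per-primary spectra.
    """
    vals = settings.values
    if vals.size != cal.n_primaries:
        raise ValueError(
            f"settings has {vals.size} entries for a {cal.n_primaries}-primary device")
    grid = cal.wavelengths
    total = np.zeros_like(grid, dtype=float)
    for i in range(cal.n_primaries):
        levels = np.asarray(cal.levels[i], dtype=float)
        stack = np.stack([sp.values for sp in cal.spectra[i]])  # (n_levels, n_wl)
        x = vals[i]
        j = np.searchsorted(levels, x, side="right")
        j = min(max(j, 1), levels.size - 1)
        w = (x - levels[j - 1]) / (levels[j] - levels[j - 1])
        total += (1.0 - w) * stack[j - 1] + w * stack[j]
    return Spectrum(grid, total, clip_negative=False)


class _RadianceModel:
    """Fast alpha-opic radiance of the forward model.

    Because the forward model is a superposition of per-primary spectra that
    are piecewise-linear in input level, and alpha-opic radiance is linear in
    the spectrum, radiance is itself piecewise-linear in each setting.  The
    per-(receptor, primary, level) radiance table is precomputed once; a
    settings vector then needs only one interpolation pass per primary.
    Identical (to float round-off) to integrating ``predict_spd`` output.
    """

    def __init__(self, cal: DeviceCalibration,
                 sens_set: Mapping[str, SensitivityFunction],
                 names: Sequence[str]):
        self.names = list(names)
        self.levels = [np.asarray(lv, dtype=float) for lv in cal.levels]
        # per primary: (n_receptors, n_levels) radiance table
        self.tables = [
            np.stack([
                np.array([alphaopic_radiance(sp, sens_set[nm]) for nm in names])
                for sp in cal.spectra[i]
            ]).T
            for i in range(cal.n_primaries)
        ]

    def radiances(self, settings: np.ndarray) -> np.ndarray:
        """Radiance vector (one entry per receptor) for a settings vector."""
        x = np.clip(settings, 0.0, 1.0)
        out = np.zeros(len(self.names))
        for i, lv in enumerate(self.levels):
            j = int(np.searchsorted(lv, x[i], side="right"))
            j = min(max(j, 1), lv.size - 1)
            w = (x[i] - lv[j - 1]) / (lv[j] - lv[j - 1])
            tab = self.tables[i]
            out += (1.0 - w) * tab[:, j - 1] + w * tab[:, j]
        return out


def _make_pair(cal: DeviceCalibration,
               sens_set: Mapping[str, SensitivityFunction],
               x: np.ndarray, objective: float, success: bool) -> StimulusPair:
    n = cal.n_primaries
    bg_set = DeviceSettings(np.clip(x[:n], 0.0, 1.0))
    pl_set = DeviceSettings(np.clip(x[n:], 0.0, 1.0))
    bg = predict_spd(cal, bg_set)
    pl = predict_spd(cal, pl_set)
    contrasts = stimulus_contrasts(bg, pl, sens_set)
    vlam = sens_set.get("V_photopic")
    return StimulusPair(
        background_settings=bg_set, pulse_settings=pl_set,
        background_spectrum=bg, pulse_spectrum=pl, contrasts=contrasts,
        background_luminance=luminance(bg, vlam),
        pulse_luminance=luminance(pl, vlam),
        objective=objective, success=success)


def _solve(cal: DeviceCalibration, problem: SilentSubstitutionProblem,
           sens_set: Mapping[str, SensitivityFunction]) -> StimulusPair:
    n = cal.n_primaries
    names = list(problem.target) + list(problem.silenced)
    rng = np.random.default_rng(problem.seed)
    floor = problem.background_floor
    bounds = [(floor, 1.0)] * n + [(0.0, 1.0)] * n

    if gamut_is_degenerate(cal, sens_set, names):
        import warnings as _warnings
        _warnings.warn("device gamut is degenerate for the requested receptors; "
                       "the solve may be ill-conditioned", RuntimeWarning,
                       stacklevel=3)

    model = _RadianceModel(cal, sens_set, names)
    full_on = model.radiances(np.ones(n))
    scale = np.maximum(full_on, 1e-300)
    idx = {nm: k for k, nm in enumerate(names)}

    cache: dict[bytes, np.ndarray] = {}

    def contrasts_at(x: np.ndarray) -> np.ndarray:
        key = x.tobytes()
        got = cache.get(key)
        if got is not None:
            return got
        bg = np.maximum(model.radiances(x[:n]), 1e-12 * scale)
        pl = model.radiances(x[n:])
        c = 100.0 * (pl - bg) / bg
        if len(cache) > 4096:
            cache.clear()
        cache[key] = c
        return c

    def contrast(x: np.ndarray, name: str) -> float:
        return float(contrasts_at(x)[idx[name]])

    if problem.mode == "maximize":
        tname = problem.target[0]

        def objective(x: np.ndarray) -> float:
            return -contrast(x, tname)
    else:
        req = float(problem.match_contrast)

        def objective(x: np.ndarray) -> float:
            cs = [contrast(x, nm) for nm in problem.target]
            mean = float(np.mean(cs))
            # pull the summary contrast onto the request and keep the
            # per-receptor spread small
            return (mean - req) ** 2 + 0.1 * float(np.var(cs))

    # Receptors with proportional radiance responses produce identical
    # contrast-constraint functions (contrast is scale-invariant), which
    # makes the SLSQP constraint Jacobian singular; keep one per signature.
    signatures: list[np.ndarray] = []
    unique_silenced: list[str] = []
    for nm in problem.silenced:
        k = idx[nm]
        sig = np.concatenate([tab[k, :] for tab in model.tables])
        norm = np.linalg.norm(sig)
        sig = sig / norm if norm > 0 else sig
        if any(np.allclose(sig, s, atol=1e-12) for s in signatures):
            continue
        signatures.append(sig)
        unique_silenced.append(nm)

    constraints = [
        {"type": "eq", "fun": (lambda x, nm=nm: contrast(x, nm) / 100.0)}
        for nm in unique_silenced
    ]
    if problem.mode == "match":
        req = float(problem.match_contrast)
        constraints.append({
            "type": "eq",
            "fun": lambda x: (np.mean([contrast(x, nm) for nm in problem.target])
                              - req) / 100.0,
        })

    def is_acceptable(pair: StimulusPair) -> bool:
        rep = verify_pair(pair, problem, sens_set)
        return rep.all_silenced_ok and (problem.mode == "maximize" or rep.target_ok)

    best: StimulusPair | None = None
    best_any: StimulusPair | None = None
    for attempt in range(problem.restarts):
        if attempt == 0:
            x0 = np.concatenate([np.full(n, 0.5), np.full(n, 0.5)])
        elif best is not None and attempt % 2 == 0:
            incumbent = np.concatenate([best.background_settings.values,
                                        best.pulse_settings.values])
            x0 = np.clip(incumbent + rng.normal(0.0, 0.1, 2 * n), 0.0, 1.0)
            x0[:n] = np.clip(x0[:n], floor, 1.0)
        else:
            x0 = np.concatenate([rng.uniform(floor, 1.0, n),
                                 rng.uniform(0.0, 1.0, n)])
        res = minimize(objective, x0, method="SLSQP", bounds=bounds,
                       constraints=constraints,
                       options={"maxiter": problem.max_iter,
                                "ftol": problem.constraint_tol})
        cand = _make_pair(cal, sens_set, res.x, float(-res.fun)
                          if problem.mode == "maximize" else float(res.fun),
                          success=False)
        if best_any is None:
            best_any = cand
        if not is_acceptable(cand):
            continue
        if best is None:
            best = cand
        elif problem.mode == "maximize" and cand.objective > best.objective:
            best = cand
        elif problem.mode == "match" and cand.objective < best.objective:
            best = cand
    if best is None:
        raise SolverFailure(
            f"no feasible pair within {problem.restarts} restarts "
            f"(silencing tolerance {problem.silencing_tolerance}%)", best_any)
    return replace(best, success=True)


def solve_max_contrast(cal: DeviceCalibration,
                       problem: SilentSubstitutionProblem,
                       sens_set: Mapping[str, SensitivityFunction] | None = None,
                       ) -> StimulusPair:
    """Maximize signed contrast on the target receptor, silencing the rest."""
    if problem.mode != "maximize":
        raise ValueError("problem.mode must be 'maximize'")
    if len(problem.target) != 1:
        raise ValueError("mode='maximize' takes exactly one target receptor")
    if sens_set is None:
        from .sensitivities import default_sensitivities
        sens_set = default_sensitivities()
    return _solve(cal, problem, sens_set)


def solve_matched_contrast(cal: DeviceCalibration,
                           problem: SilentSubstitutionProblem,
                           sens_set: Mapping[str, SensitivityFunction] | None = None,
                           ) -> StimulusPair:
    """Drive the targets' mean contrast to ``match_contrast``, silencing the rest."""
    if problem.mode != "match":
        raise ValueError("problem.mode must be 'match'")
    if sens_set is None:
        from .sensitivities import default_sensitivities
        sens_set = default_sensitivities()
    return _solve(cal, problem, sens_set)


def verify_pair(pair: StimulusPair, problem: SilentSubstitutionProblem,
                sens_set: Mapping[str, SensitivityFunction] | None = None,
                match_tolerance: float = 5.0) -> VerificationReport:
    """Recompute contrasts from the pair's spectra and check the constraints.

    The target check passes when the (summary) target contrast exceeds the
    silencing tolerance in mode ``maximize`` — i.e. the pair actually drives
    its target — or lies within ``match_tolerance`` percentage points of the
    requested contrast in mode ``match``.
    """
    if sens_set is None:
        from .sensitivities import default_sensitivities
        sens_set = default_sensitivities()
    contrasts = stimulus_contrasts(pair.background_spectrum,
                                   pair.pulse_spectrum, sens_set)
    cdict = contrasts.as_dict()
    silenced_ok = {nm: abs(cdict[nm]) <= problem.silencing_tolerance
                   for nm in problem.silenced}
    target_vals = [cdict[nm] for nm in problem.target]
    if problem.mode == "match":
        target_ok = abs(float(np.mean(target_vals))
                        - float(problem.match_contrast)) <= match_tolerance
    else:
        target_ok = abs(target_vals[0]) > problem.silencing_tolerance
    vlam = sens_set.get("V_photopic")
    return VerificationReport(
        contrasts=contrasts, silenced_ok=silenced_ok, target_ok=target_ok,
        background_luminance=luminance(pair.background_spectrum, vlam),
        pulse_luminance=luminance(pair.pulse_spectrum, vlam))


def narrowband_pair(cal: DeviceCalibration, primary_red: int, primary_blue: int,
                    ) -> tuple[Spectrum, Spectrum]:
    """Two single-primary spectra matched for unweighted total radiance.

    The primary with the larger full-output total radiance (trapezoidal
    integral over 380–780 nm) is scaled down so both totals match; all other
    primaries are off.  Returns ``(red_spectrum, blue_spectrum)``.
    """
    n = cal.n_primaries
    for p in (primary_red, primary_blue):
        if not 0 <= p < n:
            raise ValueError(f"primary index {p} outside 0..{n - 1}")

    def full_output(p: int) -> Spectrum:
        settings = np.zeros(n)
        settings[p] = 1.0
        return predict_spd(cal, DeviceSettings(settings))

    def total(sp: Spectrum) -> float:
        grid = CANONICAL_GRID
        vals = np.interp(grid, sp.wavelengths, sp.values, left=0.0, right=0.0)
        return float(np.trapezoid(vals, grid))

    red = full_output(primary_red)
    blue = full_output(primary_blue)
    t_red, t_blue = total(red), total(blue)
    if t_red <= 0 or t_blue <= 0:
        raise ValueError("both primaries must emit non-zero total radiance")
    if t_red > t_blue:
        red = red * (t_blue / t_red)
    else:
        blue = blue * (t_red / t_blue)
    return red, blue
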