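"""Synthetic pupillometry data generator.

Emulates the study protocol so every downstream stage is testable without
recorded data: each trial is a 120 Hz pupil-diameter recording with a
confidence channel, a 400–600 ms dark flash, a uniformly random 10–12 s
pre-pulse interval, a 3 s stimulus pulse and a 15 s post-pulse period.

The normalized ground-truth response g(t) (t relative to pulse onset, in %
of baseline) is a piecewise-smooth curve with the features the response
metrics measure:

* ``100`` before the response latency;
* exponential constriction ``100 − A·(1 − exp(−(t − L)/τc))`` until the
  within-pulse minimum at ``t_min``;
* linear redilation at rate ``r`` (%·s⁻¹) from the minimum to pulse offset;
* after offset, exponential recovery with time constant ``τr`` toward the
  plateau ``100 − sustained`` — a melanopsin-type condition keeps a
  sustained constriction (large τr, nonzero plateau offset), a cone-type
  condition recovers quickly to baseline.

Measured diameter = baseline·g(t)/100 + Gaussian noise, with Poisson blink
events that corrupt the diameter and zero the confidence channel — the
artifacts the masking rules are designed to catch.

Cohort generation draws per-participant physiology from group-level normal
distributions, injects configurable group effect sizes (Cohen's d, mapped
onto the generating parameter of each response metric), and produces
synthetic visual-field / OCT covariates correlated with the injected
deficit.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import RawRecording
from .spectral import Spectrum
from .stimdesign import DeviceCalibration

__all__ = [
    "PupilModelParams",
    "TrialProtocol",
    "CohortSpec",
    "CohortDataset",
    "MEL_DEFAULTS",
    "LMS_DEFAULTS",
    "RED_DEFAULTS",
    "BLUE_DEFAULTS",
    "ground_truth_curve",
    "simulate_trial",
    "simulate_cohort",
    "make_device_calibration",
    "export_supplementary_dialect",
]

STIMULI = ("Melanopsin", "LMS", "Red", "Blue")


@dataclass(frozen=True)
class PupilModelParams:
    """Parameters of the ground-truth response curve and its noise model."""

    baseline_mm: float = 4.5
    latency_s: float = 0.25
    amplitude_pct: float = 16.0
    constriction_tau_s: float = 0.20
    t_min_s: float = 1.0
    redilation_rate_pct_s: float = 3.3
    recovery_tau_s: float = 3.0
    sustained_offset_pct: float = 1.5
    noise_sd_mm: float = 0.03
    blink_rate_hz: float = 0.1
    blink_duration_s: float = 0.15
    blink_confidence: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_pct < 100.0):
            raise ValueError("amplitude must be in [0, 100)")
        if self.baseline_mm <= 0:
            raise ValueError("baseline must be > 0")
        for name in ("constriction_tau_s", "recovery_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# Condition defaults: a melanopsin-directed (and blue) stimulus leaves a
# sustained post-offset constriction; the cone-directed (and red) response
# recovers quickly.  Values are calibrated so noiseless group means land on
# the response envelope observed for each condition (documented in
# docs/methods.md as a calibration, not ground truth).
MEL_DEFAULTS = PupilModelParams()
LMS_DEFAULTS = replace(MEL_DEFAULTS, sustained_offset_pct=0.0,
                       recovery_tau_s=1.5, redilation_rate_pct_s=3.4)
BLUE_DEFAULTS = replace(MEL_DEFAULTS, amplitude_pct=30.0,
                        sustained_offset_pct=5.0, recovery_tau_s=9.0)
RED_DEFAULTS = replace(MEL_DEFAULTS, amplitude_pct=20.0,
                       sustained_offset_pct=1.0, recovery_tau_s=1.5)

CONDITION_DEFAULTS = {
    "Melanopsin": MEL_DEFAULTS,
    "LMS": LMS_DEFAULTS,
    "Red": RED_DEFAULTS,
    "Blue": BLUE_DEFAULTS,
}


@dataclass(frozen=True)
class TrialProtocol:
    """Trial timing (all seconds) and sampling rate."""

    dark_flash_range_s: tuple[float, float] = (0.4, 0.6)
    prepulse_range_s: tuple[float, float] = (10.0, 12.0)
    pulse_s: float = 3.0
    post_s: float = 15.0
    fs_hz: float = 120.0

    def __post_init__(self) -> None:
        # metrics need the trace to reach 6 s past pulse offset
        if self.post_s < 6.0:
            raise ValueError(
                "post-pulse period too short: metrics need >= 6 s past offset")
        if self.fs_hz <= 0 or self.pulse_s <= 0:
            raise ValueError("sampling rate and pulse duration must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generator configuration.

    ``effect_sizes`` maps a metric letter (``"a"``–``"d"``) to the Cohen's d
    injected between groups on the generating parameter of that metric
    (glaucoma shifted in the direction of a weaker/slower response).
    ``covariate_rho`` links the synthetic clinical covariates to the
    injected deficit severity within the glaucoma group.
    """

    n_glaucoma: int = 20
    n_control: int = 15
    n_glaucoma_redblue: int = 16
    n_control_redblue: int = 12
    trials_silent_sub: int = 30
    trials_per_narrowband: int = 15
    effect_sizes: dict = field(default_factory=dict)
    effect_stimuli: tuple[str, ...] = ("Melanopsin",)
    covariate_rho: float = 0.3
    protocol: TrialProtocol = TrialProtocol()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_glaucoma, self.n_control) < 1:
            raise ValueError("need at least one participant per group")
        if self.n_glaucoma_redblue > self.n_glaucoma or \
                self.n_control_redblue > self.n_control:
            raise ValueError("red/blue subset cannot exceed the group size")
        for v in self.effect_sizes.values():
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")


# Between-participant SDs of the generating parameters (used both for
# population heterogeneity and as the denominator of injected effect sizes).
PARTICIPANT_SD = {
    "baseline_mm": 0.6,
    "latency_s": 0.04,
    "amplitude_pct": 2.5,
    "t_min_s": 0.13,
    "redilation_rate_pct_s": 0.7,
    "sustained_offset_pct": 1.2,
}

# metric letter -> generating parameter carrying that metric's group effect,
# and the direction a *weaker/slower* glaucoma response moves it: slower to
# constrict (a: later minimum), shallower constriction (b: smaller
# amplitude), faster escape (c: higher redilation rate), less sustained
# post-offset constriction (d: smaller sustained offset).
EFFECT_PARAM = {
    "a": "t_min_s",
    "b": "amplitude_pct",
    "c": "redilation_rate_pct_s",
    "d": "sustained_offset_pct",
}
EFFECT_SIGN = {"a": +1.0, "b": -1.0, "c": +1.0, "d": -1.0}


def ground_truth_curve(t: np.ndarray, params: PupilModelParams,
                       pulse_s: float = 3.0) -> np.ndarray:
    """Analytic normalized response g(t) (%, t in s relative to pulse onset)."""
    t = np.asarray(t, dtype=float)
    g = np.full(t.shape, 100.0)
    p = params

    def constriction(tt: np.ndarray) -> np.ndarray:
        return 100.0 - p.amplitude_pct * (1.0 - np.exp(
            -(tt - p.latency_s) / p.constriction_tau_s))

    t_min = min(p.t_min_s, pulse_s)
    phase_c = (t >= p.latency_s) & (t < t_min)
    g[phase_c] = constriction(t[phase_c])

    v_min = float(constriction(np.array([t_min]))[0])
    phase_r = (t >= t_min) & (t < pulse_s)
    # within-pulse redilation saturates at baseline
    g[phase_r] = np.minimum(
        v_min + p.redilation_rate_pct_s * (t[phase_r] - t_min), 100.0)

    v_off = min(v_min + p.redilation_rate_pct_s * (pulse_s - t_min), 100.0)
    plateau = 100.0 - p.sustained_offset_pct
    phase_p = t >= pulse_s
    g[phase_p] = plateau + (v_off - plateau) * np.exp(
        -(t[phase_p] - pulse_s) / p.recovery_tau_s)
    return g


def simulate_trial(params: PupilModelParams, protocol: TrialProtocol,
                   rng: np.random.Generator) -> RawRecording:
    """One raw trial: dark flash, pre-pulse baseline, pulse, post-pulse."""
    p, proto = params, protocol
    flash = rng.uniform(*proto.dark_flash_range_s)
    prepulse = rng.uniform(*proto.prepulse_range_s)
    onset = flash + prepulse
    total = onset + proto.pulse_s + proto.post_s
    n = int(np.floor(total * proto.fs_hz)) + 1
    t = np.arange(n) / proto.fs_hz

    g = ground_truth_curve(t - onset, p, proto.pulse_s)
    diameter = p.baseline_mm * g / 100.0
    # transient dilation during the synchronisation dark flash
    in_flash = t < flash
    diameter[in_flash] *= 1.03
    if p.noise_sd_mm > 0:
        diameter = diameter + rng.normal(0.0, p.noise_sd_mm, n)
    confidence = np.clip(rng.normal(0.99, 0.005, n), 0.0, 1.0)

    if p.blink_rate_hz > 0:
        n_blinks = rng.poisson(p.blink_rate_hz * total)
        starts = rng.uniform(0.0, total - p.blink_duration_s,
                             size=n_blinks) if n_blinks else np.array([])
        for s in starts:
            sel = (t >= s) & (t < s + p.blink_duration_s)
            diameter[sel] *= rng.uniform(0.2, 0.6)
            confidence[sel] = p.blink_confidence
    diameter = np.clip(diameter, 0.05, None)
    return RawRecording(time_s=t, diameter_mm=diameter, confidence=confidence,
                        pulse_onset_s=onset, pulse_duration_s=proto.pulse_s)


def _draw_participant_params(base: PupilModelParams, rng: np.random.Generator,
                             shifts: dict[str, float], severity: float,
                             severity_params: frozenset[str] = frozenset(),
                             ) -> PupilModelParams:
    """Participant-level parameters around the condition defaults.

    Parameters carrying an injected group effect use the participant's
    latent severity as their standardized deviation (so clinical covariates
    generated from the same severity are correlated with the resulting
    pupil metrics); all others are independent normal draws.
    """
    updates: dict[str, float] = {}
    for name, sd in PARTICIPANT_SD.items():
        mean = getattr(base, name) + shifts.get(name, 0.0)
        if name in severity_params:
            updates[name] = mean + severity * sd
        else:
            updates[name] = rng.normal(mean, sd)
    updates["baseline_mm"] = max(updates["baseline_mm"], 2.0)
    updates["latency_s"] = float(np.clip(updates["latency_s"], 0.05, 0.6))
    updates["amplitude_pct"] = float(np.clip(updates["amplitude_pct"], 1.0, 60.0))
    updates["t_min_s"] = float(np.clip(updates["t_min_s"], 0.4, 2.6))
    updates["redilation_rate_pct_s"] = max(updates["redilation_rate_pct_s"], 0.0)
    updates["sustained_offset_pct"] = float(
        np.clip(updates["sustained_offset_pct"], -2.0, 40.0))
    return replace(base, **updates)


@dataclass(frozen=True)
class CohortDataset:
    """Everything the generator knows about a simulated study."""

    recordings: dict          # (participant, stimulus) -> list[RawRecording]
    ground_truth: pd.DataFrame
    clinical: pd.DataFrame
    spec: CohortSpec

    def participants(self, group: str) -> list[str]:
        sel = self.ground_truth["group"] == group
        return sorted(self.ground_truth.loc[sel, "participant"].unique())


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate the full study: both groups, all four stimulus conditions."""
    rng = np.random.default_rng(spec.seed)
    recordings: dict = {}
    gt_rows = []
    clin_rows = []

    groups = ([("glaucoma", i, f"G{i + 1:02d}") for i in range(spec.n_glaucoma)]
              + [("control", i, f"C{i + 1:02d}") for i in range(spec.n_control)])

    for group, idx, pid in groups:
        severity = rng.normal()  # latent deficit driving effects + covariates
        in_redblue = (idx < spec.n_glaucoma_redblue if group == "glaucoma"
                      else idx < spec.n_control_redblue)
        severity_params = frozenset(EFFECT_PARAM[m] for m in spec.effect_sizes)
        for stim in STIMULI:
            base = CONDITION_DEFAULTS[stim]
            shifts: dict[str, float] = {}
            if group == "glaucoma" and stim in spec.effect_stimuli:
                # constant shift of d·SD between group means = Cohen's d of d
                for metric, d in spec.effect_sizes.items():
                    pname = EFFECT_PARAM[metric]
                    shifts[pname] = shifts.get(pname, 0.0) + \
                        EFFECT_SIGN[metric] * d * PARTICIPANT_SD[pname]
            params = _draw_participant_params(
                base, rng, shifts, severity,
                severity_params if stim in spec.effect_stimuli else frozenset())
            n_trials = (spec.trials_silent_sub if stim in ("Melanopsin", "LMS")
                        else spec.trials_per_narrowband)
            if stim in ("Red", "Blue") and not in_redblue:
                n_trials = 0
            recordings[(pid, stim)] = [
                simulate_trial(params, spec.protocol, rng)
                for _ in range(n_trials)
            ]
            row = {"participant": pid, "group": group, "stimulus": stim,
                   "n_trials": n_trials, "severity": severity}
            row.update({k: getattr(params, k) for k in PARTICIPANT_SD})
            gt_rows.append(row)

        clin_rows.append(_clinical_row(pid, group, severity,
                                       spec.covariate_rho, rng))

    return CohortDataset(
        recordings=recordings,
        ground_truth=pd.DataFrame(gt_rows),
        clinical=pd.DataFrame(clin_rows),
        spec=spec)


# Group-level clinical covariate distributions (mean, SD): visual-field Mean
# Deviation and Pattern Standard Deviation (dB), mean cpRNFL thickness (µm).
CLINICAL_DISTS = {
    "glaucoma": {"md_db": (-5.72, 2.67), "psd_db": (7.67, 2.88),
                 "cprnfl_um": (62.8, 8.6)},
    "control": {"md_db": (0.52, 0.62), "psd_db": (1.43, 0.21),
                "cprnfl_um": (96.2, 7.6)},
}


def _clinical_row(pid: str, group: str, severity: float, rho: float,
                  rng: np.random.Generator) -> dict:
    row = {"participant": pid, "group": group}
    for name, (mu, sd) in CLINICAL_DISTS[group].items():
        z = rho * severity + np.sqrt(max(1.0 - rho ** 2, 0.0)) * rng.normal()
        sign = -1.0 if name == "psd_db" else 1.0  # worse fields = higher PSD
        row[name] = mu + sign * sd * z
    return row


def make_device_calibration(n_primaries: int = 10,
                            peak_wavelengths_nm: np.ndarray | None = None,
                            fwhm_nm: float | np.ndarray = 30.0,
                            max_radiance: float | np.ndarray = 0.02,
                            response_gamma: float = 1.6,
                            n_levels: int = 5,
                            rng: np.random.Generator | None = None,
                            wavelength_grid: np.ndarray | None = None,
                            ) -> DeviceCalibration:
    """Synthetic multi-primary light source calibration.

    Gaussian-shaped primary spectra (default peaks spread 420–660 nm) whose
    output scales with input level through a monotone power-law response
    (``level**gamma``), sampled at ``n_levels`` levels including 0 and 1.
    Small seeded multiplicative jitter emulates measurement noise when an
    ``rng`` is supplied.
    """
    if wavelength_grid is None:
        wavelength_grid = np.arange(380.0, 781.0, 1.0)
    if peak_wavelengths_nm is None:
        peak_wavelengths_nm = np.linspace(420.0, 660.0, n_primaries)
    peaks = np.asarray(peak_wavelengths_nm, dtype=float)
    if peaks.size != n_primaries:
        raise ValueError("need one peak wavelength per primary")
    if peaks.min() < 380.0 or peaks.max() > 780.0:
        raise ValueError("peak wavelengths must lie within 380–780 nm")
    fwhm = np.broadcast_to(np.asarray(fwhm_nm, dtype=float), (n_primaries,))
    amax = np.broadcast_to(np.asarray(max_radiance, dtype=float), (n_primaries,))
    if np.any(fwhm <= 0) or np.any(amax <= 0):
        raise ValueError("FWHM and max radiance must be positive")
    levels = np.linspace(0.0, 1.0, n_levels)

    all_levels = []
    all_spectra = []
    for i in range(n_primaries):
        sigma = fwhm[i] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        shape = amax[i] * np.exp(-0.5 * ((wavelength_grid - peaks[i]) / sigma) ** 2)
        spectra = []
        for lv in levels:
            gain = lv ** response_gamma
            vals = shape * gain
            if rng is not None and lv > 0:
                vals = vals * (1.0 + rng.normal(0.0, 0.002, vals.shape))
            spectra.append(Spectrum(wavelength_grid, vals))
        all_levels.append(tuple(levels.tolist()))
        all_spectra.append(tuple(spectra))
    return DeviceCalibration(levels=tuple(all_levels),
                             spectra=tuple(all_spectra))


def export_supplementary_dialect(mean_traces: dict, time_s: np.ndarray,
                                 out_dir, all_participants: dict) -> list:
    """Write the eight (group × stimulus) participant-mean trace tables.

    ``mean_traces`` maps (participant, stimulus) to a normalized trace on
    ``time_s`` (relative to pulse onset); ``all_participants`` maps group
    name to the full participant list for that group — participants without
    a trace for a stimulus appear as all-NA columns, marking
    non-contributors.  Returns the written file paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for group, participants in all_participants.items():
        for stim in STIMULI:
            table = pd.DataFrame({"timeRelativeToPulseOnset": time_s})
            for pid in participants:
                trace = mean_traces.get((pid, stim))
                table[pid] = np.nan if trace is None else trace
            path = out_dir / f"{group}{stim}Stimulus.csv"
            table.to_csv(path, index=False, na_rep="NA")
            written.append(path)
    return written
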