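"""Pupil-trace cleaning pipeline.

Raw pupillometer output (diameter in mm with a per-sample confidence value,
nominally 120 Hz) is cleaned in four steps, applied in this order:

1. **mask** — samples whose first-derivative of diameter falls outside
   mean ± 3 SD of the trial's derivative distribution, or whose confidence
   is below 0.95, are flagged (blinks and tracking dropouts);
2. **interpolate** — masked runs are reconstructed by linear interpolation
   between the flanking good samples (edge runs take the nearest value);
3. **smooth** — third-order low-pass Butterworth, 4 Hz cutoff, applied
   zero-phase (forward–backward) so response latencies are not delayed;
4. **normalize** — diameter is expressed as % of the baseline, the mean
   diameter over the 1 s preceding pulse onset.

Trials that are unusable (too few good samples, empty baseline, or more
than the configured fraction of masked samples) are excluded with a reason
code rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "RawRecording",
    "CleanTrial",
    "TrialExcluded",
    "mask_samples",
    "interpolate_masked",
    "smooth",
    "normalize_to_baseline",
    "preprocess_trial",
]

NOMINAL_FS_HZ = 120.0
DERIVATIVE_SD_LIMIT = 3.0
CONFIDENCE_THRESHOLD = 0.95
FILTER_ORDER = 3
FILTER_CUTOFF_HZ = 4.0
BASELINE_WINDOW_S = 1.0
DEFAULT_EXCLUDE_MASK_FRACTION = 0.25


class TrialExcluded(ValueError):
    """Trial cannot be cleaned; ``reason`` is a short machine-readable code."""

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason


@dataclass(frozen=True)
class RawRecording:
    """One trial of raw pupillometry.

    time_s is absolute within the trial; ``pulse_onset_s`` marks stimulus
    onset and ``pulse_duration_s`` the pulse length (3 s in this protocol).
    """

    time_s: np.ndarray
    diameter_mm: np.ndarray
    confidence: np.ndarray
    pulse_onset_s: float
    pulse_duration_s: float = 3.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.diameter_mm, dtype=float)
        c = np.asarray(self.confidence, dtype=float)
        if not (t.shape == d.shape == c.shape) or t.ndim != 1:
            raise ValueError("time, diameter, confidence must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "diameter_mm", d)
        object.__setattr__(self, "confidence", c)


@dataclass(frozen=True)
class CleanTrial:
    """Cleaned, onset-aligned, baseline-normalized pupil trace."""

    time_s: np.ndarray          # relative to pulse onset
    diameter_pct: np.ndarray    # % of baseline (100 = baseline)
    mask_fraction: float
    pulse_duration_s: float = 3.0

    def value_at(self, t: float) -> float:
        """Normalized diameter at time ``t`` by linear interpolation."""
        if t < self.time_s[0] or t > self.time_s[-1]:
            raise ValueError(f"t={t} s outside trace support")
        return float(np.interp(t, self.time_s, self.diameter_pct))


def mask_samples(raw: RawRecording,
                 sd_limit: float = DERIVATIVE_SD_LIMIT,
                 confidence_threshold: float = CONFIDENCE_THRESHOLD,
                 ) -> np.ndarray:
    """Boolean artifact mask (True = sample rejected).

    The derivative criterion uses the first difference divided by the
    sampling interval, with the trial's own mean and SD; a flagged
    difference masks the later sample of the pair.  The confidence
    criterion is a strict ``< threshold`` comparison.
    """
    n = raw.time_s.size
    if n < 3:
        raise TrialExcluded("too_short", f"{n} samples")
    mask = np.asarray(raw.confidence, dtype=float) < confidence_threshold
    deriv = np.diff(raw.diameter_mm) / np.diff(raw.time_s)
    mu, sd = deriv.mean(), deriv.std()
    if sd > 0:
        bad = np.abs(deriv - mu) > sd_limit * sd
        mask[1:] |= bad
    if mask.all():
        raise TrialExcluded("all_masked")
    return mask


def interpolate_masked(raw: RawRecording, mask: np.ndarray) -> np.ndarray:
    """Reconstruct masked samples by linear interpolation over time.

    Masked runs touching either end of the trace are filled with the
    nearest unmasked value (``np.interp`` end behaviour).
    """
    good = ~np.asarray(mask, dtype=bool)
    if good.sum() < 2:
        raise TrialExcluded("too_few_good_samples", f"{int(good.sum())} unmasked")
    return np.interp(raw.time_s, raw.time_s[good], raw.diameter_mm[good])


def smooth(series: np.ndarray, fs: float = NOMINAL_FS_HZ,
           order: int = FILTER_ORDER, cutoff_hz: float = FILTER_CUTOFF_HZ,
           ) -> np.ndarray:
    """Zero-phase low-pass Butterworth (default third order, 4 Hz, 120 Hz fs)."""
    series = np.asarray(series, dtype=float)
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    # sosfiltfilt needs enough samples for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if series.size <= padlen:
        raise TrialExcluded("too_short_for_filter",
                            f"{series.size} samples <= padlen {padlen}")
    return sosfiltfilt(sos, series)


def butterworth_gain(freq_hz: np.ndarray | float, cutoff_hz: float = FILTER_CUTOFF_HZ,
                     order: int = FILTER_ORDER, zero_phase: bool = True) -> np.ndarray:
    """Analytic magnitude response |H(f)| of the smoothing filter.

    For the forward–backward (zero-phase) application the effective gain is
    |H(f)|² of the single-pass Butterworth response 1/sqrt(1+(f/fc)^(2n)).
    """
    f = np.asarray(freq_hz, dtype=float)
    single = 1.0 / np.sqrt(1.0 + (f / cutoff_hz) ** (2 * order))
    return single ** 2 if zero_phase else single


def resample_uniform(raw: RawRecording, fs: float = NOMINAL_FS_HZ) -> RawRecording:
    """Linear resample onto an exact uniform grid at ``fs`` (jitter removal)."""
    t0, t1 = raw.time_s[0], raw.time_s[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    return RawRecording(
        time_s=grid,
        diameter_mm=np.interp(grid, raw.time_s, raw.diameter_mm),
        confidence=np.interp(grid, raw.time_s, raw.confidence),
        pulse_onset_s=raw.pulse_onset_s,
        pulse_duration_s=raw.pulse_duration_s)


def normalize_to_baseline(time_s: np.ndarray, diameter: np.ndarray,
                          pulse_onset: float,
                          baseline_window_s: float = BASELINE_WINDOW_S,
                          ) -> np.ndarray:
    """Express diameter as % of the mean over [onset − window, onset)."""
    time_s = np.asarray(time_s, dtype=float)
    in_window = (time_s >= pulse_onset - baseline_window_s) & (time_s < pulse_onset)
    covered = (time_s[in_window].max() - time_s[in_window].min()
               if in_window.sum() >= 2 else 0.0)
    if covered < baseline_window_s / 2:
        raise TrialExcluded("baseline_window_too_short",
                            f"{covered:.3f} s of data before onset")
    baseline = float(np.mean(diameter[in_window]))
    if baseline <= 0:
        raise TrialExcluded("nonpositive_baseline", f"{baseline:.3f} mm")
    return 100.0 * np.asarray(diameter, dtype=float) / baseline


def preprocess_trial(raw: RawRecording,
                     fs: float = NOMINAL_FS_HZ,
                     exclude_mask_fraction: float = DEFAULT_EXCLUDE_MASK_FRACTION,
                     sd_limit: float = DERIVATIVE_SD_LIMIT,
                     confidence_threshold: float = CONFIDENCE_THRESHOLD,
                     ) -> CleanTrial:
    """Full cleaning pipeline: mask → interpolate → smooth → normalize."""
    dt = np.diff(raw.time_s)
    if dt.size and (dt.max() - dt.min()) > 1e-9:
        raw = resample_uniform(raw, fs)
    mask = mask_samples(raw, sd_limit=sd_limit,
                        confidence_threshold=confidence_threshold)
    mask_fraction = float(mask.mean())
    if mask_fraction > exclude_mask_fraction:
        raise TrialExcluded("mask_fraction_exceeded",
                            f"{mask_fraction:.2f} > {exclude_mask_fraction}")
    filled = interpolate_masked(raw, mask)
    smoothed = smooth(filled, fs=fs)
    normalized = normalize_to_baseline(raw.time_s, smoothed, raw.pulse_onset_s)
    return CleanTrial(
        time_s=raw.time_s - raw.pulse_onset_s,
        diameter_pct=normalized,
        mask_fraction=mask_fraction,
        pulse_duration_s=raw.pulse_duration_s)
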