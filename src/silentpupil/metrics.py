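"""Pupil-response metrics.

Four scalar parameters summarize each normalized pupil trace (time zero =
pulse onset, pulse on for 3 s):

a. time to maximum constriction — argmin of normalized diameter within the
   pulse-on period, in ms from onset;
b. diameter at maximum constriction, % of baseline;
c. redilation rate while the pulse is on — slope of a least-squares line
   fitted to the diameter between the constriction minimum and pulse
   offset, in %·s⁻¹ (positive = redilating);
d. diameter 6 s after pulse offset (t = 9 s for a 3 s pulse), % of baseline.

The post-illumination pupil response (PIPR) is the red-minus-blue
difference in normalized diameter at a fixed time after pulse offset; a
sustained blue response (melanopsin-driven) makes it positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CleanTrial

__all__ = [
    "ResponseMetrics",
    "PiprValue",
    "GroupCurve",
    "extract_metrics",
    "participant_mean_trace",
    "compute_pipr",
    "max_group_difference_time",
]


@dataclass(frozen=True)
class ResponseMetrics:
    time_to_max_constriction_ms: float
    diameter_at_max_constriction_pct: float
    redilation_rate_pct_per_s: float | None
    diameter_6s_post_offset_pct: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "a_time_to_max_constriction_ms": self.time_to_max_constriction_ms,
            "b_diameter_at_max_constriction_pct":
                self.diameter_at_max_constriction_pct,
            "c_redilation_rate_pct_per_s": self.redilation_rate_pct_per_s,
            "d_diameter_6s_post_offset_pct": self.diameter_6s_post_offset_pct,
        }


@dataclass(frozen=True)
class PiprValue:
    participant: str
    pipr_pct: float
    t_post_offset_s: float


@dataclass(frozen=True)
class GroupCurve:
    """Per-participant mean traces on a common grid, plus the group mean."""

    time_s: np.ndarray
    participant_traces: np.ndarray   # (n_participants, n_times), NaN allowed
    group_label: str

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        traces = np.atleast_2d(np.asarray(self.participant_traces, dtype=float))
        if traces.shape[1] != t.size:
            raise ValueError("trace length must match time grid")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "participant_traces", traces)

    @property
    def group_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.participant_traces, axis=0)


def _interp_at(time_s: np.ndarray, values: np.ndarray, t: float,
               mode: str = "linear") -> float:
    if t < time_s[0] or t > time_s[-1]:
        raise ValueError(f"t={t:g} s outside trace support "
                         f"[{time_s[0]:g}, {time_s[-1]:g}]")
    if mode == "nearest":
        return float(values[np.argmin(np.abs(time_s - t))])
    return float(np.interp(t, time_s, values))


def extract_metrics(trial: CleanTrial, pulse_duration_s: float = 3.0,
                    t_post_offset_s: float = 6.0,
                    interp_mode: str = "linear") -> ResponseMetrics:
    """Extract parameters a–d from one cleaned trace.

    Requires the trace to cover [0, pulse_duration + t_post_offset] s.
    Ties in the constriction minimum break to the earliest time.  When the
    minimum falls at pulse offset there is no within-pulse redilation
    segment and the rate is reported missing (None).
    """
    t = trial.time_s
    y = trial.diameter_pct
    t_d = pulse_duration_s + t_post_offset_s
    if t[0] > 0.0 or t[-1] < t_d:
        raise ValueError(
            f"trace [{t[0]:g}, {t[-1]:g}] s does not cover [0, {t_d:g}] s")

    on = (t > 0) & (t <= pulse_duration_s)
    if not on.any():
        raise ValueError("no samples within the pulse-on period")
    t_on, y_on = t[on], y[on]
    i_min = int(np.argmin(y_on))            # np.argmin returns first minimum
    a_ms = 1000.0 * float(t_on[i_min])
    b = float(y_on[i_min])

    seg = (t >= t_on[i_min]) & (t <= pulse_duration_s)
    c: float | None
    if seg.sum() >= 2 and np.ptp(t[seg]) > 0:
        c = float(np.polyfit(t[seg], y[seg], 1)[0])
    else:
        c = None

    d = _interp_at(t, y, t_d, interp_mode)
    return ResponseMetrics(a_ms, b, c, d)


def participant_mean_trace(trials: list[CleanTrial]) -> CleanTrial:
    """Pointwise NA-aware mean across a participant's trials (common grid)."""
    if not trials:
        raise ValueError("participant contributed no usable trials")
    grid = trials[0].time_s
    for tr in trials[1:]:
        if tr.time_s.shape != grid.shape or not np.allclose(tr.time_s, grid):
            raise ValueError("trials must share a common time grid")
    stack = np.stack([tr.diameter_pct for tr in trials])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return CleanTrial(
        time_s=grid, diameter_pct=mean,
        mask_fraction=float(np.mean([tr.mask_fraction for tr in trials])),
        pulse_duration_s=trials[0].pulse_duration_s)


def compute_pipr(red_trace: CleanTrial, blue_trace: CleanTrial,
                 participant: str = "", t_post_offset_s: float = 6.0,
                 pulse_duration_s: float = 3.0,
                 interp_mode: str = "linear") -> PiprValue:
    """PIPR = red − blue normalized diameter at onset + pulse + t_post_offset."""
    t_eval = pulse_duration_s + t_post_offset_s
    red = _interp_at(red_trace.time_s, red_trace.diameter_pct, t_eval, interp_mode)
    blue = _interp_at(blue_trace.time_s, blue_trace.diameter_pct, t_eval, interp_mode)
    if np.isnan(red) or np.isnan(blue):
        raise ValueError("trace value missing at the PIPR timepoint")
    return PiprValue(participant, red - blue, t_post_offset_s)


def max_group_difference_time(curve_a: GroupCurve, curve_b: GroupCurve,
                              search_window: tuple[float, float],
                              pulse_duration_s: float = 3.0) -> float:
    """Post-offset time of maximal (curveA − curveB) group-mean difference.

    ``search_window`` is in seconds post offset; the returned value is too.
    Ties break to the earliest time.
    """
    if not np.array_equal(curve_a.time_s, curve_b.time_s):
        raise ValueError("curves must share a time grid")
    lo, hi = search_window
    if not hi > lo:
        raise ValueError("empty search window")
    t_post = curve_a.time_s - pulse_duration_s
    sel = (t_post > lo) & (t_post <= hi)
    if not sel.any():
        raise ValueError("no samples in the search window")
    diff = curve_a.group_mean[sel] - curve_b.group_mean[sel]
    return float(t_post[sel][int(np.argmax(diff))])
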