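"""Readers and writers for the file dialects used by the pipeline.

All formats are plain CSV (comma separator, ``.`` decimal, ``NA`` missing
marker, UTF-8) or JSON:

* **trace tables** — first column ``timeRelativeToPulseOnset`` (seconds,
  negative = before onset), one column per participant holding normalized
  pupil diameter in % of baseline; an all-NA column marks a participant
  who did not contribute that stimulus;
* **radiance tables** — ``wavelength`` plus the six stimulus columns
  ``MelPulse, MelBg, LMSPulse, LMSBg, red, blue`` (W·m⁻²·sr⁻¹·nm⁻¹);
* **device calibrations** — long format ``primary, level, wavelength,
  radiance`` with levels normalized to [0, 1];
* **raw recordings** — ``time_s, diameter_mm, confidence`` plus a JSON
  annotation carrying pulse onset and duration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawRecording
from .spectral import Spectrum
from .stimdesign import DeviceCalibration

__all__ = [
    "TraceTable",
    "AnalysisConfig",
    "read_trace_table",
    "write_trace_table",
    "read_radiance_table",
    "read_device_calibration",
    "write_device_calibration",
    "read_raw_recording",
    "write_raw_recording",
]

RADIANCE_COLUMNS = ("MelPulse", "MelBg", "LMSPulse", "LMSBg", "red", "blue")
TIME_COLUMN = "timeRelativeToPulseOnset"


@dataclass(frozen=True)
class TraceTable:
    """Participant-mean pupil traces for one group × stimulus condition."""

    time_s: np.ndarray
    traces: pd.DataFrame          # columns = contributing participants only
    non_contributors: tuple[str, ...]
    group: str = ""
    stimulus: str = ""

    @property
    def participants(self) -> list[str]:
        return list(self.traces.columns)

    def trace(self, participant: str) -> np.ndarray:
        return self.traces[participant].to_numpy(dtype=float)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants; defaults are the study protocol values."""

    pulse_duration_s: float = 3.0
    pipr_t_post_offset_s: float = 6.0
    pipr_search_window_s: tuple[float, float] = (0.0, 12.0)
    baseline_window_s: float = 1.0
    filter_order: int = 3
    filter_cutoff_hz: float = 4.0
    sampling_rate_hz: float = 120.0
    derivative_sd_limit: float = 3.0
    confidence_threshold: float = 0.95
    silencing_tolerance_pct: float = 6.0
    bonferroni_family: int = 4
    exclude_mask_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("pulse_duration_s", "pipr_t_post_offset_s",
                    "baseline_window_s", "filter_cutoff_hz",
                    "sampling_rate_hz", "derivative_sd_limit",
                    "silencing_tolerance_pct")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in (0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "pipr_search_window_s" in raw:
            raw["pipr_search_window_s"] = tuple(raw["pipr_search_window_s"])
        return cls(**raw)


def read_trace_table(path: str | Path, group: str = "",
                     stimulus: str = "") -> TraceTable:
    """Read a trace table; all-NA participant columns become non-contributors."""
    df = pd.read_csv(path, na_values=["NA"])
    if TIME_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required column {TIME_COLUMN!r}")
    time_s = df[TIME_COLUMN].to_numpy(dtype=float)
    if time_s.size >= 2 and not np.all(np.diff(time_s) > 0):
        raise ValueError(f"{path}: {TIME_COLUMN} must be strictly increasing")
    body = df.drop(columns=[TIME_COLUMN])
    non_contrib = tuple(c for c in body.columns if body[c].isna().all())
    traces = body.drop(columns=list(non_contrib)).astype(float)
    if traces.shape[1] == 0:
        raise ValueError(f"{path}: no participant contributed data")
    return TraceTable(time_s=time_s, traces=traces,
                      non_contributors=non_contrib,
                      group=group, stimulus=stimulus)


def write_trace_table(table: TraceTable, path: str | Path) -> None:
    out = pd.DataFrame({TIME_COLUMN: table.time_s})
    for col in table.traces.columns:
        out[col] = table.traces[col].to_numpy()
    for col in table.non_contributors:
        out[col] = np.nan
    out.to_csv(path, index=False, na_rep="NA")


def read_radiance_table(path: str | Path) -> dict[str, Spectrum]:
    """Read a mean-stimulus-radiance table into named spectra."""
    df = pd.read_csv(path)
    missing = [c for c in ("wavelength",) + RADIANCE_COLUMNS
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    wl = df["wavelength"].to_numpy(dtype=float)
    if np.any(wl < 0):
        raise ValueError(f"{path}: negative wavelengths")
    return {name: Spectrum(wl, df[name].to_numpy(dtype=float))
            for name in RADIANCE_COLUMNS}


def write_device_calibration(cal: DeviceCalibration, path: str | Path) -> None:
    rows = []
    for i in range(cal.n_primaries):
        for level, sp in zip(cal.levels[i], cal.spectra[i]):
            rows.append(pd.DataFrame({
                "primary": i, "level": level,
                "wavelength": sp.wavelengths, "radiance": sp.values}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_device_calibration(path: str | Path) -> DeviceCalibration:
    """Read a long-format calibration CSV, validating grid consistency."""
    df = pd.read_csv(path)
    needed = {"primary", "level", "wavelength", "radiance"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(needed)}")
    levels_out = []
    spectra_out = []
    for prim, dprim in df.groupby("primary", sort=True):
        levels = []
        spectra = []
        for level, dlev in dprim.groupby("level", sort=True):
            wl = dlev["wavelength"].to_numpy(dtype=float)
            order = np.argsort(wl)
            levels.append(float(level))
            spectra.append(Spectrum(wl[order],
                                    dlev["radiance"].to_numpy(dtype=float)[order]))
        levels_out.append(tuple(levels))
        spectra_out.append(tuple(spectra))
    return DeviceCalibration(levels=tuple(levels_out), spectra=tuple(spectra_out))


def write_raw_recording(raw: RawRecording, csv_path: str | Path,
                        json_path: str | Path | None = None) -> None:
    pd.DataFrame({"time_s": raw.time_s, "diameter_mm": raw.diameter_mm,
                  "confidence": raw.confidence}).to_csv(csv_path, index=False)
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump({"pulse_onset_s": raw.pulse_onset_s,
                   "pulse_duration_s": raw.pulse_duration_s}, fh)


def read_raw_recording(csv_path: str | Path,
                       json_path: str | Path | None = None) -> RawRecording:
    df = pd.read_csv(csv_path)
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    with open(json_path) as fh:
        ann = json.load(fh)
    return RawRecording(
        time_s=df["time_s"].to_numpy(dtype=float),
        diameter_mm=df["diameter_mm"].to_numpy(dtype=float),
        confidence=df["confidence"].to_numpy(dtype=float),
        pulse_onset_s=float(ann["pulse_onset_s"]),
        pulse_duration_s=float(ann.get("pulse_duration_s", 3.0)))
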