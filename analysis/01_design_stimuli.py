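"""Design the four study stimuli on the synthetic 10-primary device.

Solves the melanopsin-directed pair (maximal melanopic contrast, cones
silenced), the cone-directed control pair (summary LMS contrast matched to
325%, melanopsin silenced), and the radiance-matched narrowband red/blue
pair.  Writes spectra and a contrast report under results/stimuli/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from silentpupil.stimdesign import (SilentSubstitutionProblem, narrowband_pair,
                                    solve_matched_contrast, solve_max_contrast)
from silentpupil.synthetic import make_device_calibration

OUT = Path(__file__).resolve().parents[1] / "results" / "stimuli"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

cal = make_device_calibration()
print(f"device: {cal.n_primaries} Gaussian primaries, seed {SEED}")

mel = solve_max_contrast(cal, SilentSubstitutionProblem(
    target=("melanopsin",), silenced=("L", "M", "S"),
    mode="maximize", seed=SEED, restarts=20))
print(f"melanopsin-directed pair: {mel.contrasts.melanopsin:.1f}% melanopic "
      f"contrast, cones "
      f"{[round(getattr(mel.contrasts, c), 4) for c in 'LMS']}")

lms = solve_matched_contrast(cal, SilentSubstitutionProblem(
    target=("L", "M", "S"), silenced=("melanopsin",),
    mode="match", match_contrast=mel.contrasts.melanopsin,
    seed=SEED, restarts=20))
print(f"LMS-directed pair: mean cone contrast {lms.contrasts.lms_mean:.1f}% "
      f"(requested {mel.contrasts.melanopsin:.1f}), "
      f"melanopsin {lms.contrasts.melanopsin:.4f}%")

red, blue = narrowband_pair(cal, cal.n_primaries - 2, 2)
print("narrowband pair: radiance-matched primaries "
      f"{cal.n_primaries - 2} (red) and 2 (blue)")

wl = mel.background_spectrum.wavelengths
pd.DataFrame({
    "wavelength": wl,
    "MelPulse": mel.pulse_spectrum.values,
    "MelBg": mel.background_spectrum.values,
    "LMSPulse": lms.pulse_spectrum.values,
    "LMSBg": lms.background_spectrum.values,
    "red": np.interp(wl, red.wavelengths, red.values),
    "blue": np.interp(wl, blue.wavelengths, blue.values),
}).to_csv(OUT / "meanStimulusRadiances.csv", index=False)

report = {
    "seed": SEED,
    "melanopsin_directed": {
        "contrasts_pct": mel.contrasts.as_dict(),
        "background_luminance_cd_m2": mel.background_luminance,
        "pulse_luminance_cd_m2": mel.pulse_luminance,
        "background_settings": mel.background_settings.values.tolist(),
        "pulse_settings": mel.pulse_settings.values.tolist(),
    },
    "lms_directed": {
        "contrasts_pct": lms.contrasts.as_dict(),
        "summary_lms_contrast_pct": lms.contrasts.lms_mean,
        "background_luminance_cd_m2": lms.background_luminance,
        "pulse_luminance_cd_m2": lms.pulse_luminance,
        "background_settings": lms.background_settings.values.tolist(),
        "pulse_settings": lms.pulse_settings.values.tolist(),
    },
}
(OUT / "design_report.json").write_text(json.dumps(report, indent=2))
print(f"wrote {OUT / 'meanStimulusRadiances.csv'} and design_report.json")
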