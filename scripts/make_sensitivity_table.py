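"""Regenerate the bundled synthetic photoreceptor sensitivity table."""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from silentpupil.sensitivities import build_sensitivity_table

out = Path(__file__).resolve().parents[1] / "src" / "silentpupil" / "data" / "sensitivities_10deg_synthetic.csv"
table = build_sensitivity_table()
table.to_csv(out, index=False, float_format="%.6g")
print(f"wrote {out} ({len(table)} rows)")
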