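# silentpupil

Silent-substitution stimulus design and melanopsin-directed pupillometry
analysis, built around the question of whether pupil responses driven by
melanopsin-expressing intrinsically photosensitive retinal ganglion cells
(ipRGCs) can serve as a diagnostic biomarker for glaucoma.

Because photoreceptor spectral sensitivities overlap heavily, narrowband
light always stimulates every receptor class. *Silent substitution*
sidesteps this: a background/pulse pair of spectra on a multi-primary light
source is optimized so that exchanging them modulates one receptor class
(e.g. melanopsin, Weber contrast ≈ 325%) while leaving the others
"silent" (|contrast| < 6%). Pupil traces recorded around such pulses are
cleaned, normalized to baseline, summarized by four response parameters —
time to maximum constriction (a), diameter at maximum constriction (b),
redilation rate during the pulse (c), diameter 6 s after pulse offset
(d) — plus the post-illumination pupil response
PIPR = red − blue diameter at a fixed post-offset time, and compared
between groups with Welch/paired t-tests, Spearman correlations against
clinical covariates, and ROC analysis (Mann–Whitney AUC, DeLong 95% CI).
The binormal identity d = Φ⁻¹(sens) + Φ⁻¹(spec) links diagnostic targets
to the group separation a biomarker would need.

The package is organised as a library (`src/silentpupil/`) with numbered
analysis drivers (`analysis/`):

| module | contents |
| --- | --- |
| `spectral` | spectra, alpha-opic radiances, luminance, Weber contrasts |
| `sensitivities` | bundled photoreceptor sensitivity set (synthetic, template-derived) |
| `stimdesign` | device forward model, multi-start SLSQP silent-substitution solver, narrowband pairs |
| `preprocess` | masking, gap interpolation, zero-phase Butterworth, baseline normalization |
| `metrics` | parameters a–d, PIPR, group curves, maximal-difference timepoint |
| `stats` | Welch/paired t, Spearman, ROC + DeLong CI, Bonferroni, binormal/power analytics |
| `pipeline` | trace tables → full statistical results bundle |
| `synthetic` | protocol-faithful cohort generator with ground truth and clinical covariates |
| `io`, `cli` | CSV/JSON dialects, `silentpupil` command-line interface |

## Worked example

Design both stimulus pairs on a synthetic 10-primary device and run the
full simulated study:

```sh
python analysis/01_design_stimuli.py
python analysis/02_simulate_cohort.py
python analysis/03_group_statistics.py
python analysis/04_diagnostic_ceiling.py
```

`01_design_stimuli.py` prints

```
melanopsin-directed pair: 438.6% melanopic contrast, cones [-0.0005, -0.0002, -0.0]
LMS-directed pair: mean cone contrast 438.6% (requested 438.6), melanopsin 0.0000%
```

— a background/pulse pair with 438.6% Weber contrast on melanopsin while
all three cone contrasts are nulled to below a thousandth of a percent,
and a cone-directed control pair matched to the same summary contrast with
melanopsin silent. `03_group_statistics.py` then reproduces the study
layout on a simulated null cohort (20 glaucoma / 15 control, no injected
effect), e.g.

```
  stimulus parameter  glaucoma_mean  control_mean     p  significant_bonferroni
Melanopsin         d         97.499        97.155 0.426                   False
       LMS         d        100.190        99.867 0.439                   False

Paired melanopsin vs LMS:
parameter  n_pairs  mean_paired_difference       t      p
        d       35                 -2.7002 -9.6710 0.0000

PIPR (max-difference timepoint 11.7 s post offset):
     timepoint  glaucoma_mean  control_mean     p   auc
            6s         12.940        12.266 0.400 0.615
```

The melanopsin-directed stimulus leaves a sustained post-offset
constriction (participants' diameter still ≈ 97.5% of baseline 6 s after
offset, ≈ 2–3 points below the cone-directed condition, p < 0.001 paired)
while between-group differences are null and every AUC confidence interval
straddles 0.5 — the qualitative fingerprint of the study this package
models. `04_diagnostic_ceiling.py` prints the binormal argument for why
that matters:

```
required separation for 70% sens / 90% spec: d = 1.806 (~1.8)
equivalent binormal AUC: 0.899
power to detect d = 1.81 at n = 20/15, alpha 0.05: 99.92%
```

`05_calibration_experiments.py` closes the loop: cohorts with d = 1.8
injected on parameter d recover an empirical d of 1.78 and an AUC of 0.88
against the binormal prediction of 0.90, and 20 null cohorts give DeLong
CIs covering 0.5 in 18/20 replicates with 1/160 Bonferroni rejections.

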