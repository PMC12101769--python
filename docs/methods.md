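# Methods

`silentpupil` implements the computational chain of a melanopsin-directed
pupillometry study: design photoreceptor-isolating stimuli on a
multi-primary light source, clean raw pupil recordings, extract pupil
response metrics including the post-illumination pupil response (PIPR),
and compare a glaucoma group against controls with diagnostic-accuracy
statistics. A synthetic-data generator emulates the study protocol so the
whole chain is testable without recorded data.

## Alpha-opic radiometry

Spectral radiance `L(λ)` (W·m⁻²·sr⁻¹·nm⁻¹) is weighted by a photoreceptor's
relative spectral sensitivity `s_α(λ)` and integrated over wavelength to
give the alpha-opic radiance `∫ L(λ) s_α(λ) dλ`. All integration is
trapezoidal on a canonical 1 nm grid over 380–780 nm; inputs on other grids
are linearly interpolated, and integration is restricted to the overlap of
the supports so a step-edged spectrum does not pick up spurious half-ramp
area. Photopic luminance is `683 · ∫ L(λ) V(λ) dλ` (cd·m⁻²). Per-opsin
stimulus strength is the Weber contrast
`100·(pulse − background)/background` on these radiances; it is invariant
to a common rescaling of both spectra because the integral is linear.
Small negative measured radiances (instrument noise) are clipped to zero on
construction (configurable).

### Sensitivity functions

The bundled table `data/sensitivities_10deg_synthetic.csv` is a **synthetic
stand-in** for the standardized alpha-opic weighting functions, generated
analytically (see `sensitivities.py`): the Govardovskii A1 visual-pigment
template at the accepted in-situ peak wavelengths (L 558.9, M 530.3,
S 420.7, melanopsin 480, rhodopsin 493 nm), filtered by a smooth
ocular-media density model and peak-normalized, plus a standard
single-Gaussian approximation to photopic V(λ). Resulting corneal peaks
(S 442, melanopsin 493, rhodopsin 505, M 538, L 565 nm) are
physiologically placed, and the curves reproduce the heavy spectral overlap
that makes silent substitution necessary. They are *not* certified
colorimetric standards: absolute alpha-opic radiances computed from real
spectroradiometric data will differ by a few percent from a reference
implementation, while contrasts (ratios) are much less sensitive. Every
computation in the package uses this one set self-consistently.

## Silent-substitution stimulus design

The forward model of the light source assumes superposition across
primaries and piecewise-linear interpolation of each primary's measured
spectra across its input levels — an approximation to real device
nonlinearity that is exact at the calibration knots. Because alpha-opic
radiance is linear in the spectrum, per-receptor radiance is itself
piecewise-linear in each setting, so the solver precomputes a
(receptor × primary × level) radiance table and never re-integrates
spectra inside the optimization loop; reported contrasts agree with
contrasts recomputed from the predicted spectra to ~1e-12.

A stimulus pair is found by seeded multi-start SLSQP over the 2·n-primary
settings vector (background and pulse jointly, each within [0, 1]):

* **maximize** mode drives signed contrast on the target receptor upward
  while equality constraints hold each silenced receptor's contrast at
  zero. The user-facing silencing tolerance (default 6% absolute, the
  study's design envelope) applies at *verification*: a candidate counts as
  a success only if its recomputed silenced contrasts are within tolerance.
  Equality rather than inequality constraints are used inside the solve
  because an inequality-only formulation lets the optimizer park on the
  tolerance boundary, wasting the envelope.
* **match** mode drives the *mean* of the target receptors' contrasts to a
  requested value (an equality constraint), minimizing
  `(mean − request)² + 0.1·var(per-receptor contrasts)` so the individual
  cone contrasts stay near the request without being forced equal.
  "Overall LMS contrast" is deliberately a summary (the mean): real
  devices cannot equalize L, M and S exactly, so per-cone deviations are
  reported alongside.

Restarts begin from a neutral half-on point, from random feasible points,
and from perturbations of the incumbent; a fixed seed makes the result
reproducible, and the incumbent is monotone in the restart budget. Silenced
receptors with proportional radiance signatures produce *identical*
constraint functions (contrast is scale-invariant), which would make the
constraint Jacobian singular — duplicates are detected and collapsed before
solving. A rank check on the full-output receptor-radiance matrix warns
when the device gamut is degenerate (e.g. duplicated primaries).

Background settings have a lower bound (`background_floor`, default 0.05)
so the background radiance stays away from zero, where Weber contrast
diverges; luminance is not constrained (the pairs' pulse/background
luminances are reported, not matched). Narrowband red/blue stimuli are two
single primaries with the brighter one scaled so both have equal unweighted
total radiance over 380–780 nm.

## Pupil-trace cleaning

Raw trials (diameter in mm plus a [0, 1] confidence channel at a nominal
120 Hz) pass through four steps in order:

1. **masking** — a sample is rejected if the first difference of diameter
   (divided by the sampling interval) falls outside mean ± 3 SD of that
   trial's derivative distribution, or if confidence < 0.95 (strict).
   The derivative statistics are per-trial; the later sample of an
   offending pair is the one masked. Note the ±3 SD rule presumes
   noise-dominated derivatives: on noiseless synthetic data it flags the
   steepest physiological samples instead, which is why noise-free tests
   relax it.
2. **interpolation** — masked runs are linearly interpolated between
   flanking good samples; runs touching an end of the trace take the
   nearest good value (two-sided interpolation is impossible there).
3. **smoothing** — third-order low-pass Butterworth, 4 Hz cutoff, applied
   forward–backward (`sosfiltfilt`), so the effective gain is |H(f)|² and
   the group delay is zero: response latencies are not shifted by the
   filter. Jittered timestamps are first resampled to an exact uniform
   grid.
4. **normalization** — diameter is expressed as % of the baseline, the
   mean over the 1 s window before pulse onset; the window mean is exactly
   100 afterwards.

Trials are excluded (with machine-readable reason codes) when fully
masked, too short for the filter, missing at least half the baseline
window, or more than 25% masked (threshold configurable; the study does
not state one).

## Response metrics

On each participant's mean trace (metrics are computed per participant
mean, matching how the traces are deposited; a per-trial-then-average mode
exists for the linear metrics via `participant_mean_trace`):

* **a** — time of the in-pulse diameter minimum, ms from onset (ties break
  earliest);
* **b** — that minimum, % baseline;
* **c** — slope of a least-squares line over [t_min, pulse offset],
  %·s⁻¹, positive when redilating; undefined (reported missing) when the
  minimum falls at offset;
* **d** — diameter exactly 6 s after pulse offset, linearly interpolated
  between neighbouring samples (nearest-sample mode available).

PIPR is red-minus-blue normalized diameter at a stated post-offset time
(default 6 s); it is antisymmetric under swapping the traces. The
maximal-group-difference timepoint is the argmax of the control-minus-
glaucoma mean PIPR over a post-offset search window (default (0, 12] s),
ties earliest.

## Statistics

Welch's t-test (Satterthwaite df) for between-group comparisons with
t-based 95% CIs per group; paired t for melanopsin-vs-LMS within
participants; Spearman rank correlation (midrank ties; exact permutation
p below n = 10, t approximation otherwise) against visual-field MD, PSD
and mean cpRNFL in the glaucoma group; strict Bonferroni
(significant iff p < α/family, family = 4 parameters per stimulus). ROC
AUC is the Mann–Whitney probability with ties counting ½, reported in the
raw orientation (glaucoma = positive class; AUC < 0.5 means the effect
runs the other way), with a DeLong (midrank placement) 95% CI implemented
here because no installed package exposes the DeLong covariance; it is
cross-checked in the tests against an independent reference
implementation's output on a frozen dataset. Binormal analytics:
`d = Φ⁻¹(sens) + Φ⁻¹(spec)` for the separation a single threshold needs,
`AUC = Φ(d/√2)`, and two-sample t-test power via the noncentral t.
Degenerate inputs follow explicit conventions: both-groups-zero-variance
with equal means reports t = 0, p = 1; a constant input makes Spearman's
rho undefined and is rejected.

## Synthetic-data generator

The generator emulates the trial protocol: a 400–600 ms dark flash
(synchronization segment, with a small transient dilation), a uniform
10–12 s pre-pulse background period, a 3 s pulse and a 15 s post-pulse
period, sampled at 120 Hz. The normalized ground-truth response is a
piecewise-smooth curve — flat 100% until the response latency, exponential
constriction to a minimum at `t_min`, linear redilation (capped at
baseline) until offset, then exponential recovery toward a plateau
`100 − sustained` — the simplest form exhibiting every feature the four
metrics measure. This parametric form is an invention of this package (the
study fits no response model); condition-dependent recovery encodes the
melanopsin-vs-cone difference: melanopsin-type and blue stimuli get a slow
recovery (τ = 3 s / 9 s) toward a non-zero sustained offset, cone-type and
red stimuli recover quickly to baseline.

Default condition parameters are **calibrated so the noiseless group means
land on the study's reported values** (melanopsin: minimum ≈ 84% at
≈ 1 s, redilation ≈ 3.3%/s, 6 s post-offset diameter ≈ 97.5%; LMS
≈ 99.8%; control-group PIPR ≈ 12.8% at 6 s post offset). That is a
calibration of the simulation's operating point, not ground truth about
glaucoma. Measured diameter is `baseline · g(t)/100` plus Gaussian noise
(SD 0.03 mm), with Poisson blink events (0.1 Hz, 150 ms) that corrupt the
diameter and zero the confidence channel — exactly the artifacts the
masking rules catch.

Cohorts draw per-participant parameters from group-level normal
distributions (between-participant SDs in `PARTICIPANT_SD`). Group effects
are injected as a Cohen's d on the generating parameter of a chosen metric,
signed so glaucoma moves toward the weaker/slower response; the
participant's latent severity drives both the effect-carrying parameters
and the synthetic clinical covariates (MD, PSD, cpRNFL from the two
groups' reported distributions), linked at a configurable correlation
(default 0.3, giving the weak rho range observed). Everything is
deterministic under a fixed seed.

What the generator does *not* emulate: consensual/direct eye differences,
pharmacological dilation, ocular media differences (pseudophakia), gaze
artifacts correlated with stimulus phase, and any biophysical pupil
dynamics beyond the piecewise curve. Passing tests therefore demonstrate
that the *analysis chain* is correct and calibrated, not that real
glaucomatous pupils behave like the model.

## Problem sizes used in tests and the acceptance script

Simulation experiments run at the study's group sizes (20 glaucoma / 15
control; 16/12 for red–blue) but with reduced trial counts per participant
(4–6 silent-substitution trials instead of 30) — the participant-mean
noise at 30 trials is far below the between-participant spread, so the
extra trials change group statistics negligibly while dominating runtime.
Single-replicate empirical Cohen's d at n = 20/15 has a sampling SE of
≈ 0.4, so recovery checks average 6 seeded replicates and null-coverage
checks use 20.

## Known limitations

* Sensitivity functions are analytic approximations (above); reproducing
  published absolute contrasts from real deposited spectra to better than
  a few percent requires the certified tables.
* The forward model ignores primary interaction and thermal drift.
* The matched-contrast summary (mean of L, M, S) is one defensible choice;
  per-cone equality is exposed as a configuration but not the default.
* DeLong CIs are asymptotic; at n ≈ 12–20 per group they are rough, which
  is visible in the null-coverage experiment (≈ 90–95% empirical
  coverage).
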