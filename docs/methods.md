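# Methods

## Scope

`svagree` reimplements, as a tested library, a repeated-measures method
comparison between two beat-to-beat stroke-volume monitors — pulse wave
analysis (PWA, finger volume clamp) and suprasternal Doppler ultrasound —
under graded lower body negative pressure (LBNP) with alternating
isometric handgrip (IHG).  The raw recordings of the reference experiment
are not public, so the package pairs the analysis chain with a
synthetic-cohort generator whose defaults are calibrated such that the
full pipeline reproduces the published estimates.  The generator models
the PWA output *statistically* (a discrepancy model on top of the latent
stroke volume); it does not re-derive the device's proprietary
three-element-Windkessel algorithm.

## Protocol model

Each subject: 6-minute LBNP levels at 0, 20, 40, 60, 80 mmHg, each split
into three 2-minute periods — stabilization, then IHG and rest in an
order that is block-randomized across subjects (blocks of 2 or 4) and
alternates from level to level.  A subject's highest *completed* level is
drawn from the completion distribution of the reference cohort
(16 subjects: all completed 20 mmHg, 15 completed 40, 11 completed 60,
2 completed 80); partial levels are not generated because only completed
levels enter the analysis.  Sex follows a fixed 9-females-per-16 pattern.
Handgrip target force is 40% of the maximal voluntary contraction, itself
the mean of three simulated attempts (these quantities flow through the
data model but do not drive the hemodynamics).

## Latent hemodynamics and noise

Within a level with index ℓ (0…4) and time τ within a 2-minute period:

| quantity | model | default |
|---|---|---|
| stroke volume | SV(ℓ) = SV₀ − a·ℓ | SV₀ = 81 mL, a = 10.5 mL |
| heart rate | HR(ℓ) = HR₀ + b·ℓ | HR₀ = 62 bpm, b = 4.5 bpm |
| MAP, rest | MAP(ℓ) = MAP₀ + c·ℓ | MAP₀ = 85 mmHg, c = 6.825 mmHg |
| MAP, IHG | + boost·τ/120 s | boost = 17.94 mmHg |
| SVR (emergent) | MAP / (SV·HR/1000) | ≈17 at rest → ≈30+ at depth |

Beats tile each period deterministically from the heart-rate trajectory
(optional R-R jitter, default off); the first beat of a period starts at
the period boundary, so phase labels are unambiguous.

Measured signals add noise at three scales:

* **beat scale** — independent Gaussian noise per beat (SV 2.0 mL, MAP
  1.5 mmHg); mostly removed by 30-s aggregation;
* **30-s bin scale** — independent per-method Gaussian errors shared by
  all beats of a bin (US 1.869 mL, PWA 1.863 mL); this is what the
  method-precision statistic sees;
* **level scale** — the disagreement residual ε(subject, level) with SD
  σ_within = 4.742 mL (below).

The method discrepancy for a beat of subject *i* on level ℓ is

    SV_PWA − SV_US(latent) = δ₀ + β·(SVR_latent − SVR_ref) + u_i + ε_iℓ

with δ₀ = 27.0 mL at SVR_ref = 22.04, generative β = 0.5626 mL per
mmHg·min·L⁻¹ (sex-specific variant: 0.8154 male / 0.3415 female),
u_i ~ N(0, 13.99²) and ε_iℓ ~ N(0, 4.742²).

**Why the disagreement residual lives at the level scale.**  The printed
estimates demand simultaneously a per-method precision of ±3.7 mL
(residual variability of 30-s values at rest) and a within-subject LOA of
±11.1 mL (residual variability of the *difference* across all analysis
bins).  If ε were independent per 30-s bin, its SD would have to be
11.1/1.96 ≈ 5.7 mL and the PWA precision would inflate to ≈ ±11.7 mL.
Real monitors disagree in a state-dependent way: placing ε at the
(subject, level) scale reproduces both statistics — it varies within a
subject across levels (feeding the within-subject LOA) but is constant
across the rest bins of level 0 (leaving precision untouched).  The
time-proxy model's (1 | subject:level) random effect absorbs exactly this
term.

## Calibration of the defaults

The defaults are the fixed point of `scripts/calibrate_defaults.py`:
simulate replicate cohorts, run the full pipeline, and adjust one
parameter per target quantity until the *recovered* estimates match the
reference values (bias 27.0, LOA ±30.1, within-subject LOA ±11.1,
mean-of-methods slope −0.15, SVR slope 0.60, per-sex slopes 0.86/0.40,
time-in-IHG slope 0.58 mL/30 s, precision ±3.7 mL per method).  Two
couplings make this calibration non-trivial and are worth knowing about:

* **Errors in variables.**  The pipeline computes SVR_US from the
  *measured* SV_US, as the reference analysis does.  Measurement noise in
  the regressor attenuates the fitted slope, and the shared SV_US noise in
  the difference and in SVR_US adds a small positive covariance; the net
  effect is that a generative β of 0.5626 yields a fitted slope of 0.60.
  Only in the zero-noise limit does the fit return β exactly (kept as a
  property test).
* **Difference noise leaks into the mean.**  The mean of methods contains
  half the difference, so the level-scale residual pushes the sloped-bias
  slope toward positive values; the level-driven SVR rise
  (`map_rise_per_level`) is calibrated against this so the fitted slope
  lands at −0.15 mL/mL.

The baseline SV₀ = 81 mL is not free: it is the resting Doppler stroke
volume implied by the reference BSA-indexed value (43.2 mL/m² × 1.874 m²
at the cohort-mean height/weight), and together with the dropout-weighted
level mix it puts the grand mean of methods near 76 mL, consistent with
the printed percentage errors.

What the generator does **not** emulate: waveform morphology beyond a
schematic systolic bump / half-sine ejection (the waveform synthesizer
exists to test the MAP/VTI operations, not to model physiology),
autonomic transients other than the linear IHG ramp, presyncope symptoms
beyond the stop level, and any mechanistic PWA model.  Passing
parameter-recovery tests therefore show the *statistical machinery* is
correct and the calibration coherent — not that the generator predicts
real hemodynamics.

## Preprocessing rules

* Beats within [release, release + 30 s) of any IHG release are dropped
  (half-open window, membership by beat onset) — the release transient is
  too fast for either monitor.
* Beats on levels above a subject's stop level are dropped.
* 30-s bins are aligned to period starts so the ordinal bin index (0–3)
  within a 2-minute period is well-defined for the time-proxy model.
* Per bin and per variable independently, the aggregate is a symmetric
  trimmed mean removing ⌈0.05·n⌉ values per tail — the ceiling keeps
  trimming active at the ~25–50 beats a bin holds.  Heart rate is the
  trimmed mean of instantaneous 60/RR.
* Bins with fewer than 5 beats are dropped with a warning.
* Stabilization bins are produced and flagged but excluded from the
  agreement models by default (`AnalysisOptions.include_stabilization`);
  the reference analysis is ambiguous on this point.

## Statistical models

All models are linear mixed models estimated by REML (statsmodels
`MixedLM`), subject random intercept, variance components truncated at
zero, 95% Wald intervals, two-sided p-values.  LOA = 1.96·√(σ²_b + σ²_w)
about the fitted bias (line); within-subject LOA = 1.96·σ_w.  The
percentage-error denominator is the grand mean of the per-bin mean of
methods (a per-subject-first variant is available).  The time-proxy model
adds a variance component for LBNP level nested in subject and uses the
ordinal 30-s bin index as the time variable, so its slope is in mL per
30 s.  Sex-specific SVR slopes are linear combinations of the interaction
fit with delta-method (Wald) intervals.

Numerical choices: optimizer L-BFGS with a tight BFGS polish on small
problems (≤500 records), so that on balanced designs the REML components
match the closed-form ANOVA estimators to 1e-6; fits whose response is
exactly reproduced by subject fixed effects (zero residual noise — the
degenerate corner where the profiled REML criterion is ill-conditioned)
are solved exactly by a direct path instead.  Degenerate designs (a
single subject, a constant covariate, one sex with an interaction
requested) are refused with a `ModelSpecificationError` rather than
silently fitted.

## Problem sizes

Parameter-recovery checks run 20 replicate cohorts of 200 subjects
(default and sex-specific calibrations), comparing each Monte-Carlo mean
with its reference value at 3 Monte-Carlo standard errors.  These sizes
give standard errors a few times smaller than the published confidence
intervals while keeping a full run in the low minutes on one core.

## Known limitations

* LOA are reported without confidence intervals (none are published for
  the reference quantities); no bootstrap.
* The two printed percentage errors (14.6% constant-bias, 13.4% sloped)
  share one denominator and cannot both be matched exactly by a single
  variance structure; the calibrated pipeline gives ≈14.0% / 13.4%.
* CVP is fixed at 0 in SVR (an optional argument exists for sensitivity
  analyses); no pressure-dependent CVP model.
* No Deming/ordinary regression comparison, concordance or polar trending
  statistics — the scope is the mixed-model Bland–Altman family above.
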