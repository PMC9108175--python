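# Methods

`wristcut` implements a laboratory validation pipeline for intensity
cut-points applied to wrist-worn ActiGraph accelerometer data in
school-aged youth, together with a synthetic-cohort generator that makes
the whole pipeline testable without access to participant-level data.
This note records the models, the constants, and the design choices made
where the design was genuinely open.

## The validation design being emulated

Adolescents complete 12 structured activity trials (lying down,
handwriting, computer game, laundry, throw-and-catch, sweeping,
comfortable walk, dance, fast walk, treadmill walk, basketball, run)
wearing tri-axial accelerometers on both wrists while oxygen uptake is
measured breath-by-breath with a portable calorimeter. Each trial lasts
5 min (lying down: 10 min). Features are extracted from minutes 2.5–4.5
(lying: 7.0–9.0), a 120-s analysis window chosen to sit on the
steady-state plateau. Steady state requires heart rate within ±5 bpm and
VO₂ within 10% of their window means.

Ground-truth intensity uses **Youth METs**: window-mean VO₂ relative to
body mass, divided by *predicted* resting VO₂ (not the adult
3.5 ml·kg⁻¹·min⁻¹). Resting energy expenditure comes from the Schofield
weight-and-height equations for children (3–10 y and 10–18 y bands, by
sex), converted from MJ/day to ml O₂·kg⁻¹·min⁻¹ with an energy
equivalent of oxygen of 20.9 kJ/L (configurable). The weight+height
variant is used because height is listed among the predictors of the
protocol; the coefficients live in one auditable table
(`energy.SCHOFIELD_COEFFICIENTS`). Categories: sedentary requires a
lying/sitting posture *and* < 1.5 Youth METs; light is < 3 (an upright
trial below 1.5 is light, not sedentary); moderate is [3, 6); vigorous
is ≥ 6. Posture comes from the activity catalogue, not from the signal.

Seven published cut-point sets are evaluated (four Crouter sets for the
dominant wrist on vertical-axis or vector-magnitude counts per 5 s, two
Chandler sets for the non-dominant wrist, and the Hildebrand ENMO
threshold set for the non-dominant wrist). Each set stores its own
boundary semantics as printed: Crouter sedentary thresholds are
inclusive (x ≤ 105 is sedentary), Chandler prints SED < 161 / LPA ≥ 162,
which implies integer counts, so 161 is stored as an inclusive sedentary
bound (non-integer means in (161, 162) fall to light); Hildebrand's
ENMO bound is exclusive (x < 35.6). Moderate/vigorous bounds are
lower-inclusive everywhere. The two Crouter regression sets carry their
linear METs equations; classification nevertheless uses the printed
count thresholds (which are the equations inverted at 3 and 6 METs and
rounded), and `regression_mets` is exposed separately for reporting.

Agreement uses weighted Cohen's kappa, κ_w = 1 − Σw·o / Σw·e with
disagreement weights w_ij = |i−j|/3 (linear, the default), ((i−j)/3)²
(quadratic) or 0/1 (unweighted), with the large-sample
(Fleiss–Cohen–Everitt) variance and a normal 95% interval clipped to
[−1, 1]. The weighting scheme is configurable because the emulated
analysis does not state one; linear is the conservative default for an
ordinal 4-category outcome. A table with a single occupied row and
column has chance agreement 1; kappa is then reported as undefined
rather than forced to a number. Confusion matrices are oriented rows =
measured, columns = predicted; per-class accuracy is the diagonal over
the row sum, with empty classes reported as missing. Direction
summaries count predictions above/equal/below the measured category per
activity using the SED < LPA < MPA < VPA order.

## Signal processing

**ENMO** is computed per sample as max(0, ‖a‖ − 1) g on calibrated data,
averaged over 1-s epochs and reported in milli-g; trial-level
classification uses the mean over the analysis window (at the window
level, 1-s and 5-s epoching reduce to the same mean). **Vector
magnitude** of counts is the per-epoch Euclidean norm of the three axis
counts. Epochs are half-open [t, t + len) with times in seconds from
trial start.

**Autocalibration** estimates per-axis gain and offset from still
periods: non-overlapping 10-s windows with per-axis SD < 13 mg
contribute their mean vectors, which should lie on the unit gravity
sphere. An iterative closest-point least-squares fit (regress each
axis's sphere projection on its current value, compose the correction,
stop when the mean absolute norm residual changes by < 1e-6, cap 100
iterations) recovers the calibration. The fit is only attempted when at
least 10 still windows exist *and* they cover the sphere (each axis
reaching ±0.3 g); otherwise identity parameters are returned flagged as
not converged — on a single-posture recording a 6-parameter sphere fit
is not identifiable, and doing nothing is safer than extrapolating. The
still-SD threshold and sphere criteria follow common practice for
in-situ autocalibration of wrist accelerometers and are config-exposed.
In the pipeline, calibration is fitted per participant and side on the
concatenation of that device's trials, so still periods from different
postures jointly condition the fit.

## The synthetic cohort generator

The generator's defaults *are* the emulated study conditions: 18
participants (10 male, 8 female), ages normal(14.6, 2.4) truncated to
[8, 18] (note the truncation shifts the realized mean to ≈ 14.24 y),
right-handedness probability 0.9, 12 trials each, and an independent
per-trial dropout probability of 34/216 with a reason drawn from the
four protocol failure modes, so a default cohort retains ≈ 182 of 216
trials. Mass and height come from growth-chart-style age/sex medians
with lognormal spread (13% and 4% log-SD) — they only need to make
predicted REE realistic.

Per trial and activity, the generator draws:

* **Youth METs** ~ normal(m, s) truncated at ≥ 1, with (m, s) the
  reported per-activity mean and SD.
* **Trial-mean VA, VM and ENMO** from lognormal distributions fitted to
  the reported per-activity median and IQR: μ = ln(median) and σ solving
  the IQR-width equation q75 − q25 = 2·median·sinh(z₇₅σ) (closed form
  via asinh). Metrics whose reported median is zero use a zero-inflated
  lognormal with inflation 0.5 and spread 0.5 (log scale) whose upper
  quartile matches the report; a zero lower quartile with positive
  median uses inflation 0.25 with μ, σ matching the mixture's median and
  upper quartile. Counts are non-negative and right-skewed, which is
  what a lognormal encodes.
* **Coupling.** A latent Gaussian copula links the draws: the METs
  latent and a trial "movement level" latent correlate at 0.7, the two
  wrists share the movement latent with cross-wrist correlation 0.8, and
  each metric loads on its side latent at 0.95. The met–movement
  coupling is the generator's one structural assumption beyond the
  reported marginals: within an activity, children who move more expend
  more energy. Without it, sedentary-trial metric draws are independent
  of sedentary METs and the high sedentary classification accuracy seen
  in such studies is not reproduced.

From the draws, the signals are synthesized:

* **VO₂** ramps from predicted resting VO₂ onto the plateau implied by
  the drawn METs with first-order on-kinetics (τ = 45 s), sampled on the
  15-s grid with 2% multiplicative noise — small enough that the
  steady-state check passes by default but fails occasionally, as in
  real protocols. **Heart rate** is 70 + 12·(METs − 1) bpm following the
  same ramp, with 1.5 bpm noise.
* **Counts** are simulated directly at the 5-s epoch level (the
  raw-to-counts filter is proprietary; validation studies treat counts
  as given device output). Epoch values are the drawn trial mean times
  multiplicative burst noise (log-SD 0.25), rescaled so the
  analysis-window mean equals the draw exactly; VM ≥ VA is enforced and
  the VM residual is split randomly between the ML and AP axes before
  rounding to integers.
* **Raw acceleration** is a slowly drifting unit gravity vector (random
  base orientation per trial) plus band-limited (0.3–4 Hz) oscillation
  and 3 mg device noise. Each trial begins with a 15-s quiet settling
  interval followed by a 30-s amplitude ramp — outside the analysis
  window, but giving the autocalibration still windows at one more
  orientation per trial. The oscillation amplitude is tuned by bisection
  so the window-mean ENMO equals the drawn target. An optional per-device
  gain/offset distortion is applied last (default off: the emulated
  devices are factory calibrated; enable it via
  `calibration_gain_halfrange` / `calibration_offset_halfrange_g` to
  exercise autocalibration end to end).

Everything is deterministic given (config, seed); datasets re-written to
CSV are byte-identical.

**What the generator does not emulate.** Trial means match reported
medians/IQRs, but the joint distribution across activities within a
participant (a fast kid is fast everywhere) is not modelled, nor are
non-wear, posture transitions inside the window, device clock drift, or
the spectral signature of specific movements; counts and raw signal are
generated in parallel rather than via the proprietary filter, so
count–ENMO correlation within an epoch is only as strong as the latent
copula. Consequently, passing tests show the *pipeline arithmetic* and
the *qualitative misclassification structure* are right; they do not
certify agreement statistics on real children. In particular the exact
kappa values of the emulated study (0.45–0.58) depend on unavailable
participant-level data; the simulated cohort lands in the same moderate
band by construction of the marginals, not by fitting.

## Numerical choices and degenerate inputs

Bisection for the ENMO amplitude runs 40 iterations on [0, 8] g
(resolution ≪ 1 mg); if the target is below the noise floor the
amplitude is zero. The truncated-normal and lognormal draws go through
quantile transforms of the latent normals, so coupling never distorts
the marginals. Windows shorter than required, series under 60 s for
autocalibration, empty analysis windows, negative counts, METs
boundaries (1.5/3/6 exactly) and single-cell confusion matrices all
have explicit contracts (error or flagged result) exercised by tests.

## Problem sizes

The default study (18 × 12 trials, both wrists, 30 Hz) simulates in
seconds and evaluates end to end in under a minute on one core. The
generator-fidelity check uses 500 trials per activity, which is enough
to pin each simulated median well inside sampling noise of its target
IQR.

## Known limitations

* The Chandler integer-gap convention and the Crouter open-interval
  semantics for non-integer means are interpretations of printed
  thresholds; both are isolated in the per-set `sed_inclusive` flag.
* The slow-walk underestimation fraction for the tightest threshold set
  (CR_ROC_VA, MPA ≥ 262 counts/5 s) has an expectation of ≈ 0.5 under
  the reported slow-walk count distribution (median 250, IQR 220–287):
  at ~15 trials per activity this direction check is near a coin flip
  for that one set, whichever way the latent coupling is set.
* Autocalibration quality depends on orientation diversity; recordings
  with a single posture are left uncalibrated by design.
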