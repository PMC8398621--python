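# Methods

This note records the model, the synthetic study conditions, and the
numerical choices behind them, in enough detail to re-derive or challenge
any of them.

## The estimation problem

One stride (gait cycle, GC) is represented as 100 time-normalized samples
referenced to heel strike; stance occupies 0–60% and swing 60–100% of the
cycle. The input is the total plantar pressure — the sum of ten insole
channels, kPa — over one GC; the target is the knee joint angle over the
same GC in the lateral-video convention (≈180° at full extension, flexion =
180° − angle). Both streams are min-max scaled with bounds fitted on the
training split only (one global pair of bounds per stream per dataset;
per-position scaling is available via configuration but is not the
default).

## Sensor model

The textile sensor is a parallel-plate capacitor, C = ε_r ε₀ A / d. Its
bench calibration is piecewise linear in relative capacitance change
(ΔC/C₀): slope 0.232 MPa⁻¹ up to 11.00 kPa, 0.070 MPa⁻¹ beyond
(saturation). The literature value is printed per MPa without naming the
ordinate; we interpret sensitivity as d(ΔC/C₀)/dP — the standard convention
for capacitive pressure sensors — making the curve dimensionless,
continuous at the breakpoint, strictly increasing, and hence exactly
invertible (the inverse is used to turn counts into kPa). The dielectric's
relative permittivity is taken as 1.2 for the nonwoven fabric; it only sets
C₀, which cancels in ΔC/C₀, so downstream results do not depend on it.
Shear stress, hysteresis and temperature drift are out of scope.

## Synthetic study conditions

The generator emulates 2-minute treadmill trials for a cohort of young,
healthy women: body mass ~ N(50.40, 2.20²) kg, comfortable speed
~ N(2.40, 0.30²) km/h, fast speed ~ N(5.10, 0.20²) km/h (resampled until
fast > comfortable). Values the protocol does not pin down were chosen once
as field-plausible defaults:

* **Cadence**: C ~ N(44, 2²), F ~ N(62, 3²) strides/min — implied by the
  above speeds at typical stride lengths (0.9–1.25 m).
* **Range-of-motion multiplier** per subject: N(1.0, 0.03²) clipped to
  [0.8, 1.2]. The tight spread reflects the deliberately homogeneous cohort
  (age 20.7 ± 0.8 y, height 1.58 ± 0.04 m); it is also the scale at which a
  pressure-only model can transfer across subjects, which the design
  requires (see "What passing tests show" below).
* **Sensor noise**: per-channel white Gaussian, sd ~ max(N(0.05, 0.01²),
  0.01) kPa, plus a treadmill-vibration sinusoid of 0.06 kPa at 27.5 Hz
  with random phase per channel — deliberately above the 15 Hz filter
  cutoff so the Butterworth stage demonstrably removes it. Pressure is
  clipped at zero after noise addition. The angle stream is noise-free.
* **Waveforms**: the total pressure is a stance-only double bump built from
  sin² bumps — a heel-strike bump on [0, 0.36] of the cycle (with a small
  step at contact: the impact transient) and a push-off bump on
  [0.30, 0.60], exactly zero in swing. The summed waveform tracks the
  vertical ground reaction force and is therefore the same for all three
  shoes; heel height instead *redistributes* the two loads across channels
  (share vectors over rearfoot/midfoot/forefoot that each sum to one, with
  the forefoot share growing by 0.7·(heel shift) for the heel load), so
  the forefoot fraction of the stance impulse rises S1 < S2 < S3 while the
  total is footwear-independent. Speed scales the push-off bump (0.95 C /
  1.15 F) and the summed peak (×1.10 at F); the peak is calibrated to
  0.55 kPa per kg body mass (an 80 kg subject fully supported on the
  minimal 188 cm² insole area corresponds to ≈42 kPa).
* **Knee angle**: flexion = ROM · [speed·16°·bump(2–28%) + 8°·bump(40–62%)
  + speed·heel·58°·bump(53–97%)] + 2°, with speed factor 0.92 C / 1.08 F
  and heel factor 1 − 0.025·(heel_cm − 1) applied to the swing bump only
  (the stiff-knee effect of high heels). Swing flexion peaks near 75% GC.
* **Timing**: cycle durations are the subject's cadence with ±3% uniform
  per-cycle jitter, snapped to whole 100 Hz samples; pressure (100 Hz) and
  angle (30 Hz) share the cycle clock, and exact heel-strike/toe-off times
  are kept in trial metadata for validation.

Ten channels split 4 forefoot / 2 midfoot / 4 rearfoot (configurable).

### Cycle phase conventions

Cycles are segmented toe-off→toe-off (Zero-To-Zero), exclusive of the
closing event sample, then resampled to 100 points with endpoints
preserved and circularly rotated to the detected heel strike. Accordingly
the generator's reference pressure template samples phases k/100 and its
angle template phases k/99 (angle cycles are sliced inclusive of both
bounding heel strikes). At 60 strides/min the 1.00 s cycle aligns with the
100 Hz grid and the pressure round trip is exact; the angle round trip is
limited only by linear interpolation of the 30 Hz stream (<1° for these
templates).

## Preprocessing

Order: trim to the centered minute → 10-point trailing moving average
(partial window at the leading edge; the trimmed margins make edge effects
irrelevant) → 4th-order Butterworth low-pass at 15 Hz, applied
forward-backward so gait-event timing is preserved (single-pass available
via config) → channel sum → segmentation. The zero threshold defaults to
2% of the 95th percentile of the total-pressure trace (scale-free, robust
to the noise floor); the pipeline additionally requires 25 consecutive
loaded samples (0.25 s) before accepting a toe-off, and 5 consecutive
loaded samples for the heel strike inside a cycle, to reject noise-floor
chatter. Segments deviating more than 40% from the median duration are
discarded as artifacts; the 30 (31, counting the closing heel strike for
angle pairing) segments nearest the window center are kept.

The smoothing stages exist for noise: the 10-point moving average has
5–10% passband droop at the 2–4 Hz content of the stance double bump, so
no noiseless template round trip through it can be sub-percent. The
template-recovery validation therefore runs the chain with the denoising
stages disabled (window 1, no Butterworth, threshold ~0) — testing
segmentation, resampling and rotation exactly — while the filters' own
contracts (unit DC gain, passband within 2% at 2 Hz, stopband <5%
amplitude at 30 Hz) are tested separately. The full default chain is what
the end-to-end experiment uses.

## Training protocol

Glorot-uniform initialization, zero biases, ELU α = 1.0. RMSprop with
learning rate 0.007, squared-gradient decay 0.9, ε = 10⁻⁸; MSE loss on the
normalized cycles; 50 epochs; batch 32; every random draw (cohort, noise,
initialization, shuffling, dropout) derives from one experiment seed.

Validation is leave-one-subject-out over the training subjects: one fold
per subject, each training on the remainder and recording per-epoch
train/validation losses. Two numerical choices stabilize the deployed
model and are deliberate deviations worth knowing about:

* the deployed model is **refit on all training subjects** after the folds
  (cross-validation monitors generalization; the final model uses every
  training cycle);
* the returned weights are the **best-training-loss iterate** of the run
  rather than the epoch-50 endpoint. Constant-rate RMSprop at 0.007
  bounces around the optimum (epoch-end MSE oscillates by 1.5–2×), so the
  endpoint is a high-variance draw; taking the best iterate on the
  training objective removes that lottery without involving validation
  data (no early stopping).

Prediction de-normalizes the network output and smooths it with a
zero-phase 4th-order Butterworth at 0.2 cycles/sample in the 100-point
domain (evaluation uses the post-filter output). The CNN comparison model
follows the identical protocol; dropout is seeded during training and
disabled at inference; its dense layer has 100 units (unspecified in the
reference architecture); "3 × 3" kernels and "2 × 2" pooling are read as
kernel length 3 and pool length 2 for 1-D convolutions.

The hidden-layer-1 activation is the standard logistic 1/(1+e^(−h)); the
printed form of that equation in the source literature (1/(1−e^h)) is
singular at h = 0 and is treated as a typographical sign error — the
function is named Sigmoid there.

## Evaluation

Metrics are computed per test cycle and averaged over the cycles of each
model × shoe × speed cell. MRE and R are kept exactly in their printed
forms — MRE divides by the *prediction* (asymmetric), and R is the
coefficient-of-determination form 1 − SS_res/SS_tot (a Pearson correlation
is logged alongside for diagnostics; which of the two the original tables
report is not decidable from the text). Bland-Altman uses one point per
test gait cycle (the cycle-mean difference, prediction − actual), bias =
mean, LoA = bias ± 1.96 sample SD (n−1); a per-sample mode is available via
config.

## What passing tests do and do not show

The synthetic cohort makes the pipeline falsifiable end to end: exact
ground-truth segmentation, templates recoverable to machine precision, and
held-out accuracy bounds (worst-cell MRE ≤ 15%, worst-cell R ≥ 0.75) that
the default conditions are designed to support. Real data differ in ways
the generator does not emulate: subject-specific waveform *shapes* (not
just amplitudes), kinematic variability uncorrelated with plantar
pressure, video-tracking noise in the reference angle, sensor drift and
hysteresis, and overground (non-treadmill) gait. Passing here validates
the implementation and the statistical machinery, not clinical accuracy.
The hardest cell is consistently the stiletto at comfortable speed — the
smallest knee excursion, hence the smallest signal variance in R's
denominator — and with 5 training subjects the worst-cell R fluctuates by
roughly ±0.05–0.1 across cohort seeds; occasional draws can dip slightly
below 0.75 on that cell, the same cell family where the original
experiment reports its own minimum.

## Problem sizes

Default experiment: 7 subjects × 6 conditions × 120 s trials; 30 cycles
per condition (1,260 cycle pairs); six MLPs, each 5 LOSO folds + 1 refit
of 50 epochs. The whole experiment runs in ~30 s on one CPU; the CNN
comparison on the 900-cycle all-condition dataset adds ~2 minutes.
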