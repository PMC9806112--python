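# Methods

## Scope and data model

The package detects binary upper-limb use from wrist-worn IMU data
(triaxial accelerometer in g, gyroscope in deg/s, optional magnetometer,
nominal 50 Hz) recorded on both arms, with ground truth given by four
binary annotation tracks (two annotators × two passes) at video rate
(30 Hz), a task track and a movement-type track (Arm / Hand /
NonFunctional). Datasets live in a flat CSV, one row per 50 Hz
timestamp; annotation tracks are upsampled to the sensor grid by
zero-order hold on write. Missing samples are handled solely by
zero-order-hold resampling — no interpolation ever invents values, which
matters for binary and categorical tracks. The consensus ground truth is
the majority vote of the four tracks with 2–2 ties resolved to
*non-functional*, the conservative choice for a construct defined by the
presence of meaningful movement.

## Pre-processing and orientation

- **Rest detection**: a rest period is ≥ 10 s in which every gyroscope
  axis has sample variance < 0.15 (deg/s)². The threshold is read as a
  variance (not an SD) and is applied per 1 s non-overlapping block;
  runs of ≥ 10 quiet blocks are merged. Block evaluation is O(N),
  deterministic, and coincides with a window scan whenever quiet and
  active stretches are cleanly separated, which is the regime the rule
  is meant for.
- **Gyro offset correction**: the per-axis mean over each rest period is
  subtracted from all samples from that rest period's start to the next
  one's start; data before the first rest period is untouched. The
  correction is therefore piecewise constant and shape-preserving.
- **Accelerometer median filter**: 5th-order running median per axis,
  shrinking windows at the edges, NaN-aware (missing samples are
  excluded from their windows), removing sharp jumps and isolated
  dropouts.
- **Sensor fusion**: Madgwick's gradient-descent filter (6-DOF,
  β = 0.1) is the default orientation source; Mahony's complementary
  filter (9-DOF with magnetometer, Kp = 1, Ki = 0.3) is used inside the
  activity-count measure. Both are implemented in-package in the
  standard formulation, with the initial quaternion tilt-aligned from
  the first accelerometer sample to shorten convergence. Gains are the
  algorithms' published defaults and are exposed in the configuration.
- **Angle conventions**: quaternions are scalar-first, sensor-to-earth.
  Pitch is the elevation of the sensor x axis (the forearm long axis,
  pointing toward the hand) above the horizontal plane, in [−90°, 90°];
  yaw is its heading in (−180°, 180°]. Yaw is unwrapped before any
  windowed range computation so the ±180° seam cannot fake movement.

On simulated trajectories the Madgwick pitch tracks the generating truth
with RMSE < 1° after the first 5 s (the test budget allows 3°).

## Measures

Implementation choices where the source pipelines are under-specified:

- Band-pass filters are 4th-order Butterworth applied forward-backward
  (zero-phase), so counts stay aligned with the annotations; offline
  processing makes the non-causality harmless.
- VM: per-axis dead-band at ±0.068 g, absolute values summed over 1 s
  bins anchored at the first timestamp, 2-norm across axes, then a 5 s
  moving average with 1 s hop (i.e. 4 s overlap) stamped at window end —
  exactly 1 Hz.
- AC: 1 s bin means of the band-passed magnitude, quantized by
  floor(x / 0.017 g); an epsilon (1e-9) in the floor guards against
  binary-float artefacts such as 0.034/0.017 evaluating just below 2.
- Laterality: LI = (c_dom − c_nondom)/(c_dom + c_nondom), the only
  orientation of the ratio consistent with the ±0.95 threshold
  semantics; seconds with zero counts on both arms have an undefined LI
  and are flagged unused on both arms.
- GM: Δyaw and Δpitch are window ranges (max − min); the functional-
  space condition uses the window-mean pitch; both thresholds strict.
- GMAC: VM counts at 1 Hz; bin-mean pitch from the Madgwick series over
  the 1 s bin ending at the counts timestamp.

## Machine-learning protocol

0.25 s non-overlapping windows are defined as *time bins*: at 50 Hz a
window holds alternately 12 and 13 samples, and a 10 s record yields
exactly 40 windows. The window label is the consensus sample at the bin
centre (start + 0.125 s, zero-order hold); a trailing partial window is
dropped. Features use population variance (the window is the population
of interest) and a KDE entropy with an *absolute* Gaussian bandwidth of
0.2 g evaluated at the sample points — not a spread-scaled bandwidth, so
a constant window has the closed-form entropy log(√(2π)·0.2).

Nested cross-validation is implemented by hand so leakage is assertable:
the outer loop is a stratified 5-fold split (repeated with reshuffling;
default 10 iterations), the inner loop a stratified CV over the outer
training rows only, selecting hyper-parameters by mean inner Youden
index. Every result records the row indices touched during selection,
and the test suite asserts they are disjoint from the outer test fold.
Grids: RF trees ∈ {10, 50, 100, 200}; SVM C ∈ {0.1, 1, 10, 100},
γ ∈ {0.001, 0.01, 0.1, 1} (RBF, inverse-frequency class weights,
features z-scored with training statistics inside the pipeline); the MLP
has a fixed 32/16 two-hidden-layer architecture and no grid. The MLP
trains to tolerance-based convergence rather than early stopping:
holding out 10% of a few-hundred-row window table as a validation set
reliably under-trains the network, which is a property of small tables,
not of the architecture.

## Evaluation

Use signals (1, 2 or 4 Hz) are aligned to the 50 Hz consensus grid by
zero-order hold and scored sample-wise (tp/fp/tn/fn → sensitivity,
specificity, Youden J = sens + spec − 1). Measure families are compared
with a one-way ANOVA plus pairwise Welch t-tests (unequal variances
across families are the rule, not the exception) with Bonferroni
correction. The class-proportion analysis regresses per-recording
sensitivity and specificity on the percentage of functional data
(computed from the consensus ground truth) by OLS and reports slope and
slope p-value. The task ablation retrains the intra-subject RF under the
four train/test compositions of a task's presence/absence, pooling
outer-fold confusion counts per condition; windows labelled `unknown`
(inter-task transitions) are excluded.

## Synthetic generator

The generator is a scripted state machine over four movement regimes:

| regime | pitch | yaw | motion accel | label |
|---|---|---|---|---|
| functional arm | base U(−20°, 20°) ± 6° | bursts: sinusoids, amplitude U(15°, 35°), 0.25–0.5 Hz, separated by 1–2 s holds | bursts of 0.1–0.4 g, 0.5–2 Hz | use = 1, Arm |
| functional hand | U(−25°, 25°), slow 1.5° wobble | ±2° | 0.01–0.04 g at 1.5–3 Hz (down at the noise floor) | use = 1, Hand |
| gait | −75° ± ~12° at 1 Hz | ±5° at 1 Hz | pendular 0.15–0.3 g at 1 Hz | use = 0, NonFunctional |
| rest | constant U(−15°, 15°) | constant | none | use = 0, NonFunctional |

Epochs are joined by 1 s cosine ramps labelled task `unknown`,
non-functional. True yaw/pitch trajectories drive an exact forward
model: body-frame specific force = Rᵀ(gravity + earth-frame motion
accel), gyroscope = the body angular rates implied by the scripted
angles (ω = (ψ̇ sin p, −ṗ, ψ̇ cos p) for roll 0) plus a constant
per-axis offset (default (0.5, −0.3, 0.2) deg/s) and noise, magnetometer
= a fixed dipping earth field rotated into the body frame. Defaults:
accelerometer noise 0.01 g, gyroscope noise 0.2 deg/s — rest-epoch gyro
variance 0.04 (deg/s)² sits safely under the 0.15 rest threshold.

Annotation tracks are produced at 30 Hz from the true use label with two
noise mechanisms per annotator-pass: every label transition is displaced
by a reaction time N(0, 0.3 s) (video annotators do not mark epoch
boundaries frame-exactly), then labels flip independently with
probability 0.02. Boundary jitter is what gives learned detectors a
realistic, class-prior-dependent error floor; the hand regime's
noise-floor accelerations are what keeps counting measures from seeing
hand-dominant use. Neither is a claim about any particular annotator
pool — both are configurable.

A target functional share rescales functional vs non-functional epoch
durations while preserving total duration; targets that would squeeze a
rest block under 10 s raise an error reporting the achievable share.
The default cohort is 15 subjects — 10 controls (arms `left`/`right`)
and 5 patients (`affected`/`unaffected`), the affected arm generated
with half movement amplitude and a 0.30 functional-share target. Both
arms of a subject use the same task multiset (shuffled order), so their
1 Hz count grids match for the laterality computation.

### What the generator does and does not emulate

It reproduces the *structure* the measures key on: gravity-consistent
accelerometry, functional-space geometry, gait arm-swing at hanging
pitch, ≥ 10 s rest blocks, per-axis gyro bias, annotator noise. It does
not emulate biomechanical detail (no roll dynamics, no within-task
variety of real reaching, no magnetic disturbances, no soft-tissue
artefacts). Passing tests therefore show the algorithms implement their
definitions and reproduce the comparative structure under these
conditions — not that any measure achieves a particular accuracy on real
patient data.

## Problem sizes and determinism

The default simulated arm is ~133 s (≈530 feature windows); the
data-factor sweep uses nine ~550 s single-arm recordings with target
shares 0.1–0.9. Cohort-level test runs use one CV iteration and a
reduced RF grid ({50, 100} trees, 3 inner folds); the full protocol
(10 iterations, 4-point grid) is the library default. All randomness
flows from explicit seeds (NumPy `default_rng` / SeedSequence; per-arm
streams derived from (seed, subject, arm)), so every pipeline output is
bit-reproducible at a fixed seed.

## Known limitations

- The laterality measure needs both arms on a common grid; recordings
  of unequal length are truncated to the shorter arm.
- Mahony yaw depends on the magnetometer reference and is only defined
  up to the simulated declination; the measures use yaw only through
  windowed ranges, which are reference-free.
- GM's yaw is ill-conditioned when the forearm points straight down
  (pitch ≈ −90°); the functional-space condition masks this region, but
  yaw-range values there should not be interpreted.
- The annotation-noise model is symmetric; real annotator disagreement
  is likely structured (e.g. systematically late marks).
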