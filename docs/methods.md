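# Methods

`pose2grf` implements a complete desk-scale replica of a markerless
motion-analysis workflow: 2D pose keypoints from sagittal video are turned
into three-component ground reaction force (GRF) estimates with a
bidirectional LSTM, and three pose-estimator variants are compared for
detection completeness and interchangeability. Because the kind of
video/force dataset this workflow targets is not publicly distributable, the
package ships a synthetic gait generator that plays the role of the data
while every analysis stage operates exactly as it would on real recordings.

## The estimation problem

A trial is a runner crossing a force plate at 4.5–5.5 m/s, filmed at 25 FPS
sagittally while the plate samples the GRF at 2000 Hz. Pose estimation
yields per-frame keypoints; only the eight joint centres used here —
bilateral shoulder, hip, knee, ankle — are retained. The stance phase
(vertical force > 20 N) plus 15 lead-in and 10 lead-out frames forms the
analysis window. The network learns the map

  inputs `[n × 101 × 16]` → targets `[n × 101 × 3]`,

where inputs are hip-centred pixel coordinates (joint-major, x before y) on
a 101-point normalised-time grid and targets are the mass-normalised GRF
components (medio-lateral, anterior–posterior, vertical) in N/kg.

## Preprocessing chain

Fixed order: window extraction → gap interpolation → Savitzky–Golay
smoothing (order 3, window 5, polynomial edge fits) → cubic-spline
upsampling to 200 Hz → translation to a moving frame centred on the hip
mid-point → stance crop → time normalisation to 101 frames. Interior
keypoint gaps are closed by per-axis linear interpolation; gaps touching the
first or last window frame cannot be interpolated and invalidate the trial
(full-window or stance-only, depending on reach). Event frames are mapped
to the 200 Hz grid by rounding to the nearest sample. Force records are
cropped to the detected stance (strict 20 N threshold on the vertical
component), decimated 2000→200 Hz, resampled to the keypoint stance sample
count (the keypoint stream is authoritative for the frame count),
mass-normalised and time-normalised to 101 frames. Force data are not
filtered anywhere.

## Network and training

Two stacked bidirectional LSTM layers (400 units per direction at the
reference configuration), dropout 0.5 between layers, and a per-timestep
affine head to the three components; MSE objective, Adam at learning rate
0.003, batch size 16, 40 epochs, with the weights of the epoch with the
smallest validation loss retained. Inputs and targets are z-scored per
channel with constants computed on the training data only; the constants
travel with the model and predictions are returned in N/kg. Dropout is
applied between layers only, not inside the recurrent connections. The
network is implemented in numpy with analytic backpropagation-through-time
(verified against central finite differences in the test suite) and
optional numba-compiled recurrent kernels; training runs in float32, the
standard working precision for this model class.

Cross-validation is leave-one-subject-out. Within each fold one training
subject (seeded choice) is held out as the validation set, so train,
validation and test sets are subject-disjoint by construction. Three test
cases are enumerated per fold: #1 train and test on the same estimator's
keypoints, #2 test on a different estimator's keypoints with the same
fitted model, #3 train on all estimators' keypoints pooled. With 10
subjects and 3 estimators the plan comprises 40 fits (30 single-estimator,
10 pooled).

## Evaluation statistics

Per trial and component: Pearson r and RMSE normalised by the ground-truth
range, averaged over components then trials for the summary grids (the
pooled-over-frames alternative is also computed). Intensity parameters:
Fmax is the maximum of the Euclidean norm of the 101-frame mass-normalised
GRF; the instantaneous loading rate (ILR) is the OLS slope of the vertical
component from stance onset to the first local maximum (impact peak), with
a fallback window of the first 13 % of stance on peakless curves — both are
computed on the normalised-time curve, the quantity the network predicts,
so the time-scale constant cancels in all paired comparisons. Scalar
comparisons use two-sided paired t-tests (α = 0.05) and paired Cohen's d
(mean of differences over their SD), banded trivial/small/moderate/large/
very large at 0.20/0.60/1.20/2.0 with boundaries to the lower band.
Whole-curve comparisons use a statistical-parametric-mapping style test:
pointwise paired t over the 101 frames with family-wise control from a
sign-flip permutation of the paired differences and a max-|t| null (1000
permutations by default, identity flip always included). A 200-simulation
null calibration keeps the family-wise false-positive rate at α within
binomial error; the test suite re-runs that calibration.

Reporting follows the conventions of the interchangeability design: grid
columns are the training estimator; row #1 is same-estimator testing, rows
#2X are cross-estimator testing on estimator X, row #3 the pooled model.
Δabs = truth − estimate; Δpercent = 100·(estimate − truth)/truth, so
negative Δpercent means underestimation. Cumulative load converts a
per-step Fmax deficit to kN over a session: Δ[N/kg] · steps · mass / 1000.

## Synthetic world

The generator emulates the study conditions rather than any particular
dataset:

* **Cohort** — mass ~ N(62.77, 5.41²) kg truncated above 40 kg, stature
  ~ N(168, 4²) cm, leg length 0.53 ± 0.008 of stature; 10 subjects and 97
  running trials by default (the post-exclusion scale such studies end up
  with).
* **Kinematics** — sum-of-sinusoids joint trajectories driven by a stride
  phase locked to heel strike (heel strike is a stride-phase event; a trial
  re-times it only by a small jitter), projected to a sagittal pixel frame
  at 1 m ≙ 400 px. The camera is treated as subject-tracking, so residual
  drift is small and frame-to-frame displacements stay below 50 px.
* **Forces** — vertical: impact lobe (≈0.36 of the active amplitude,
  peaking near 13 % of stance) plus an active half-sine, scaled so the peak
  equals `peak_factor · m · g` exactly; anterior–posterior: full-period sine
  (braking then propulsion, mid-stance zero crossing, ≈0.25 BW); medio-
  lateral: low-amplitude sine with randomised sign and phase — deliberately
  carrying almost no signal recoverable from sagittal keypoints, which is
  what makes the medio-lateral component hard for the network, as it is in
  practice for single-camera sagittal setups. Force is exactly zero outside
  stance. Stance duration ~ N(0.22, 0.015²) s.
* **Amplitude coding** — the trial's vertical peak factor is
  2.5 BW + 0.014·(apparent hip-to-ankle extent − reference)px + N(0, 0.10) BW,
  clipped to [2.0, 3.0] BW. The mean of 2.5 BW puts mass-normalised Fmax
  near 24.5 N/kg; the 0.10 BW trial-to-trial noise (~4 % CV) matches
  realistic step-to-step peak variability. The extent coupling is the
  mechanism that makes estimator conventions matter (below).
* **Estimator variants** — tag A (reference) and tag O add independent
  zero-mean 2 px Gaussian noise; tag B follows a different joint-centre
  convention, shifting knee and ankle toward the hip by 4 % of the apparent
  leg length (≈14 px) before adding its own noise. Mean A–O displacement is
  therefore ~0 while A–B differs systematically by an order of magnitude
  more — so models trained on A or O keypoints systematically underestimate
  force when fed B keypoints. The reverse direction (trained on B, tested
  on A/O) then shows a systematic difference of the opposite sign: a
  monotone amplitude-coding mechanism cannot produce same-signed mean
  shifts in both directions, so the package's claim for the reverse
  direction is "systematically different", not "underestimated".
* **Missingness** — Bernoulli dropout per (frame, joint) cell with separate
  interior and window-boundary rates per estimator. Boundary rates
  (A 0.001, O 0.0035, B 0.027) follow from the closed form
  P(valid full window) = (1−p)^16, chosen so expected full-window detection
  rates sit near 98 / 94 / 65 % with stance-only rates near 100 % — the
  qualitative ordering such comparisons report, with B far weakest.

What the generator does **not** emulate: image content (no occlusion
physics, lighting or true pose-estimator failure modes), ground-truth
kinematic constraints during stance (the planted foot still follows the
analytic oscillation), non-running movements beyond plausible placeholder
waveforms, and any real between-subject waveform covariance structure.
Passing tests therefore demonstrate that the pipeline machinery and the
statistical reasoning behave correctly and that the interchangeability
logic detects the kind of systematic convention shift it was designed to
detect — not that any particular accuracy level would be attained on real
video.

## Problem sizes and numerical choices

The reference network (400 units) is what the configuration defaults
express; the shipped experiment runs — the acceptance script and the
qualitative test — use 48 units per direction and 40 epochs at the full
10-fold LOSO plan, a desk-scale setting chosen so a complete study trains
in minutes on one CPU core while leaving the qualitative pattern intact.
The SPM calibration uses 200 null simulations of 10 pairs with 1000
permutations each. Savitzky–Golay edge frames are fitted with the
polynomial on the truncated window; cubic splines are used for keypoint
resampling and linear interpolation for force resampling; stance-event
times are mapped between rates by rounding to the nearest sample; the 20 N
stance threshold is strict (>), which makes the all-zero and
constant-at-threshold edge cases deterministic. Permutation thresholds use
the (1−α) quantile of the max-|t| null with the identity flip included,
which errs conservative.

## Known limitations

* The medio-lateral component is unpredictable by design; its r hovers near
  zero and its nRMSE near 1, dominating averaged summaries exactly as a
  hard component would.
* Fmax and ILR are computed on the 101-frame curve rather than the raw-rate
  curve; on the synthetic waveform family the difference is below 0.5 %.
* MSE-trained curve regression smooths the sharp impact transient, whose
  timing varies across trials; predicted early-stance slopes are therefore
  systematically shallower than the truth and ILR is underestimated by a
  broadly condition-independent margin in the shipped desk-scale runs. Fmax
  (dominated by the smooth active peak) is unaffected, which is why the
  interchangeability conclusions rest on Fmax and the r/nRMSE grids.
* With few LOSO folds, per-subject regression-toward-the-mean biases do not
  cancel and same-estimator Fmax deltas can reach a few percent; the full
  plan restores cancellation. Run at least the full fold set before reading
  the Fmax significance table.
* A validation subject is consumed per fold, so training sets are one
  subject smaller than a maximal LOSO would allow.
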