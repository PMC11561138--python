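# Methods

This note documents the models, algorithms, numerical choices and
limitations of `kneeload`, module by module.

## Synthetic gait laboratory (`kneeload.synthetic`)

The simulator replaces a motion laboratory and the musculoskeletal
simulation pipeline that would normally supply ground truth. It is planar
(sagittal): out-of-plane motion appears only as orientation noise, which is
sufficient because every estimator in the package is sagittal.

**Cohorts.** Ages are truncated-normal 29 ± 6 y on [20, 45]; BMI 25.1 ± 4.2
on [18.8, 40.4]; sex Bernoulli with P(male) = 29/46; height normal by sex
(165 ± 6.5 / 178 ± 7 cm, truncated to [150, 200]); mass = BMI·(height/100)².
Comfortable speed is truncated-normal 133.56 ± 20 cm/s on [80, 200] —
anchored to the population mean of healthy adult gait; the per-subject
spread is a modelling choice, since only pooled statistics are published
for such cohorts. Instructed "slow"/"fast" trials scale the comfortable
speed by exactly 0.75/1.25. An osteoarthritis-like pre-training cohort is
older (62 ± 8 y), heavier (BMI 29.5 ± 4.5) and slower (110 ± 18 cm/s).

**Kinematics.** Each trial opens with 0.5 s of neutral standing (the zero
reference for IMU orientation differencing), a 0.3 s lead-in blend, then
six strides. The gait period defaults to `1.05·(1.34/v)^0.42` s (cadence
rises with speed v in m/s; clipped to [0.7, 1.6] s) and stance occupies
0.62 of the cycle, a typical value for level walking. Stance knee flexion
follows a double-bump template through (heel-strike flexion 2–6°, early
peak a₁ ∈ [10, 25]° at 25% stance, late minimum a₂ ∈ [0, 8]° at 78%,
toe-off a₂ + 1.5–4°); swing rises to 58–68°. Template breakpoints snap to
the sample grid so the trial's KFA predictor ground truth is exactly
a₁ − a₂. During each stance the supporting ankle is pinned to a fixed
ground anchor and the thigh angle is solved in closed form from the
two-link chain (thigh 0.245·height, shank 0.246·height — standard
anthropometric fractions, configurable), so foot stationarity — the
assumption the IMU speed estimator relies on — holds exactly. The hip
advances at the true speed with a small (±1 cm, twice per cycle) periodic
oscillation and constant nominal height; the hip height is 0.96·leg length,
so the "ground" is a virtual reference rather than a contact constraint.
Swing interpolates the thigh angle with cosine easing between the
closed-form stance boundary values; the deliberate velocity mismatch at
foot strike produces the impact transient that gait-event detectors key on.

**Loads.** A generative linear model maps (mass, height, age, sex, speed,
KFA) to the summed-compartment LR and TE peak heights (default
coefficients give ≈ 2.5 kN summed peaks, ≈ 3.3 body weights, at cohort
means); a medial share (0.62 ± 0.03 per trial) splits compartments, and the
curves are two non-overlapping raised-cosine bumps at 25% / 75% stance, so
extracting peaks from the curve recovers the generated heights exactly.
Gaussian noise (SD 150 N) perturbs the realized peaks; non-positive
pre-clip predictions flag the trial degenerate. Because the generative
model is linear, the network and the linear baseline should perform
equivalently on synthetic data — which is exactly the structural relation
the end-to-end checks assert.

**Sensors.** Seven IMUs (pelvis, thighs, shanks, feet) report orientation
from forward kinematics and specific force from twice-differentiated
sensor positions plus gravity, expressed in the sensor frame. The
"realistic" noise preset uses low-passed (5 Hz) angular noise of 2° SD per
axis — a soft-tissue-artefact-like wobble; white per-frame noise would be
unrepresentative and would bias any max-minus-min statistic — plus 0.6 m/s²
white accelerometer noise.

**Camera.** A fixed virtual sagittal camera (default 480×272 px at
0.009 m/px, i.e. a ≈ 4.3 m field of view) projects hips, knees, ankles and
a synthetic head landmark placed 0.936·height above the standing ankle
level (the anthropometric ankle-to-vertex ratio used for scale
calibration). Out-of-frame keypoints are encoded as OpenPose-style
(0, 0, 0) triplets. With occlusion enabled, the far-side leg's landmarks
lose confidence (×0.15–0.45) and drift up to 3 px toward the near leg
during the near leg's mid-swing — emulating how a single camera degrades
when the analyzed leg is hidden. Trial invalidity is a Bernoulli flag
(p = 0.1), standing in for the visual ground-reaction-force inspection a
laboratory would perform.

**What the simulator does not model:** ground-reaction forces, marker
trajectories, soft-tissue artefact proper, 3D camera geometry, multi-person
scenes, pathological gait. Passing tests therefore show that the
*algorithms* are correct and robust to the modelled noise, not that the
same accuracies will be reached on real captures.

## Feature extraction (`gait_features`)

The KFA predictor splits the stance window at `start + floor(len/2)`
(first half closed-left/open-right — a deterministic tie rule). Loading
peaks: local maxima are detected on a 5-sample moving average (strictly
greater neighbours) and the *raw* curve value at the detected index is
reported, so smoothing locates but never attenuates a peak; LR is the
largest local maximum in the first half of stance, TE in the second; if a
half has no interior local maximum (lateral curves can lack the double
bump) the plain maximum over that half is used. Full-stance max is
max(LR, TE) by construction. The exact peak-picking recipe used by
laboratory pipelines varies; both the smoothing window and the rule are
config-visible constants. The allometric strength scale factor
1.5·(mass ratio)^(2/3) is provided as a standalone utility.

## IMU pipeline (`imu_pipeline`)

Heel strikes are peaks of the 10 Hz low-passed shank acceleration
magnitude with ≥ 0.5 s separation and prominence ≥ 0.5·SD of the filtered
signal (parameters sized for normal-walking cadence; all exposed). Speed:
foot positions relative to the pelvis come from rotating thigh/shank
vectors (height fractions, same defaults as the simulator) by their sensor
orientations; the pelvis is dead-reckoned by pinning the most recently
struck foot, with two timing choices that matter: the anchor *handover*
happens 6% of a period after each strike (inside double support, tolerant
of event-timing error), and stride lengths are sampled 25% of a period
after each strike (mid-stance, when the foot is reliably flat). Strides
whose duration deviates > 35% from the median are discarded as lead-in or
edge artifacts. Speed is the mean of 3D stride length / stride duration —
using vector norms keeps the estimate invariant to any rigid world-frame
rotation. Flexion: per sensor, orientations relative to the neutral first
frame are converted to rotation vectors; the first principal axis (SVD of
the centred vectors) is the flexion axis and the signed projection the
rotation angle; knee flexion = shank − thigh rotation with the sign fixed
so flexion is positive on average (the swing phase dominates). A
motionless sensor (degenerate principal axis) contributes zero rotation
and borrows the other sensor's axis. Without a force plate, the stance
window for the KFA predictor is heel strike → heel strike + 0.62·period,
averaged over interior stances.

## Video pipeline (`video_pipeline`)

All quantities are computed from vector geometry in pixel space, making
them invariant to mirroring (walking direction), translation and uniform
scaling. Analysis is restricted to the span where the hip is confidently
tracked, since a fixed camera sees only part of the walkway. Scale:
95th-percentile head-to-ankle pixel extent over confident, centre-frame
frames, compared with 0.936·height; an explicit override is available for
calibrated setups. Speed: least-absolute-deviations fit of hip x vs time
(robust to dropouts and occlusion outliers), absolute slope × scale.
Flexion: 180° minus the hip–knee–ankle included angle; frames below the
0.3 confidence threshold are linearly interpolated (keeping uniform
sampling), and a light Savitzky–Golay smoother (window 11, order 3;
disable with `smooth_window=0`) suppresses pose-network jitter. Stance
windows come from ankle stationarity: the supporting foot is still in the
image while the body passes over it, so runs (≥ 0.25 s) of low smoothed
ankle pixel speed are stances — positions are smoothed *before*
differentiation because raw jitter would swamp the near-zero stance
velocity. The per-trial KFA predictor averages over gait-plausible stance
windows (duration within 0.6–1.5× the median; edge windows dropped when
enough remain).

## Prediction models (`prediction_models`)

Exactly one hidden tanh node per response: ŷ = a·tanh(w·x + b₁) + b₂ on
min–max-[−1, 1]-normalized inputs *and* output (output normalization keeps
the α/β scales balanced). Training is damped Gauss–Newton
(Levenberg–Marquardt, μ ∈ [1e−12, 1e10], ×0.1 on success / ×10 on
rejection, accept-only-improvement) on F = β·E_d + α·E_w with E_d the sum
of squared residuals and E_w the sum of squared parameters (biases
included). Every 5 accepted iterations the evidence framework re-estimates
the hyperparameters: H = β·JᵀJ + α·I, γ = N_w − α·tr(H⁻¹) clipped to
(0, N_w], α = γ/2E_w, β = (N − γ)/2E_d with small floors for the degenerate
noiseless case. Initialization is a bounded-uniform Nguyen–Widrow-style
draw from the config seed, so training is bit-reproducible. This is the
standard meaning of "Bayesian-regularization backpropagation"; numerical
parity with any particular commercial implementation is not claimed.
Pre-training fits normalization on the pooled pre-train + fine-tune data,
trains on the first dataset, and continues optimization on the second;
because steps are accept-only, fine-tuning can never end worse on its own
objective than the pre-trained starting point. Sex is coded female = 0,
male = 1. The MLR baseline is ordinary least squares with an explicit
rank check; inactive predictors (the four predictor sets are demographic /
+KFA / +speed / full) get zero coefficients. Models serialize to
version-tagged JSON.

## Evaluation (`evaluation`)

Balancing: a subject is excluded if *any* of the six walking
configurations has fewer than five valid trials; otherwise exactly the
first five valid trials per configuration (by trial order) are kept — 30
per subject. NRMSE normalizes the pooled RMSE by the mean of the pooled
reference values. Pearson R is flagged undefined (NaN) on zero-variance
input. Predictor metrics are inter-subject means of intra-subject RMSE/R
with *population* (n) SDs of the per-subject values — the n vs n−1 choice
is not dictated by convention here and is fixed and documented. The
MAE-change table reports (MAE_modality − MAE_baseline)/MAE_baseline per
subject × direction. Statistical testing (repeated-measures ANOVA etc.) is
deliberately out of scope; `observations.csv` is the tidy long-format
input such software needs.

## Workbench and problem sizes

`run_experiment` chains data → models → predictions → report with files as
the only inter-stage contract, a manifest recording the config hash, and
stage-level resume. Defaults: 20 test subjects × 6 configurations × 10
trials, 100 training subjects × 18 trials, 40 pre-training subjects — sizes
chosen so a full experiment completes in about a minute on one CPU while
leaving enough trials per configuration for the balancing filter to act.
The acceptance script uses 24 test subjects × 8 trials per configuration
for its end-to-end stage and 500 random curves for the peak-extraction
comparison, for the same reason.

## Known limitations

- The generative load model is linear by design; nonlinear superiority of
  the network (observed on some lateral peaks in real data) cannot emerge
  from this simulator.
- The KFA predictor may legitimately be negative for atypical flexion
  curves; no clamping is applied.
- IMU orientations are consumed as given (as with commercial sensor
  fusion); raw gyro/accelerometer fusion, magnetometers and drift are out
  of scope.
- The video pipeline assumes a single person, no lens distortion, and a
  sagittal view.
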