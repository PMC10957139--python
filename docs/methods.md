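# Methods

This note documents the models and procedures implemented in `earmotion`,
the assumptions behind the synthetic data generator, the numerical choices
that matter, and what the bundled benchmarks do and do not demonstrate.

## Conventions

Accelerometer channels are in g, gyroscope channels in deg/s, sampling at
`fs` Hz (100 Hz throughout the studies). Orientation uses intrinsic Z-Y-X
Euler angles (yaw ψ, pitch θ, roll φ), right-handed, with the body-to-world
rotation R = R_z(ψ)R_y(θ)R_x(φ); a level sensor reads +1 g on body z
(accelerometers measure specific force). Quaternions are scalar-first unit
quaternions. Angles are wrapped to (−180°, 180°]; angle errors are computed
on the wrapped difference.

Accelerometer tilt angles are
roll = atan2(A_y, √(A_x²+A_z²)), pitch = atan2(−A_x, √(A_y²+A_z²)).
The pitch sign is fixed by requiring that the accel-derived angle equal the
generator's ground-truth pitch under the convention above; this joint
validation (generator ↔ filters) is exercised directly by the tests.

## Sensor calibration

Gyro static bias is the per-axis mean of a nominally static recording
(the studies use 10 s); the accelerometer follows the six-position model
S_i = G_i·A_i + B_i, inverted as A_i = (S_i − B_i)/G_i. The calibration
round-trip is exact by construction and property-tested.

## Synthetic data generator

The generator stands in for a 45-participant study dataset that is not
required here. It emulates:

* **Head rotations** — raised-cosine angular-velocity pulses
  (rate = A/T_p·(1 − cos 2πu/T_p)) whose integral is exactly the commanded
  angle, with zero rate at phase boundaries; simple movements are
  origin→target→origin, complex ones visit two targets. Peak rate defaults
  to 60 deg/s. Body rates come from the exact Euler-rate kinematic map, so
  quaternion integration of the rates reproduces the Euler trajectory to
  discretization error (< 0.1° with trapezoidal rates at 100 Hz).
* **Activities** — class-characteristic signal families on top of the
  body-frame gravity vector: gait harmonics with class-specific cadence and
  amplitude (walk 1.8 Hz/0.12 g < jog 2.8 Hz/0.35 g), free-fall/impact
  pulse trains for jumping, turning as slow gait plus a constant ±25 deg/s
  yaw rate (turning right is the exact gyro-z mirror of turning left),
  low-variance gravity-dominated postures with distinct mean orientations
  and micro-motion signatures (standing 0.035 g at 0.4 Hz, sitting 0.08 g
  at 0.9 Hz, lying 0.012 g at 0.25 Hz), and falling as repeated
  fall-and-recover cycles (~8 s period: stand, 0.45 s free-fall, 3 g
  impact, lying, rise). The micro-motion amplitudes are deliberately above
  the sensor noise floor so the posture classes are separable in
  vector-sum statistics, and the fall class is cyclic so that every
  analysis window of a fall trace contains fall-related dynamics —
  matching per-trace labeling. Per-participant style (amplitude, cadence,
  phase, posture tilt) is drawn once per participant to support
  leave-participant-out evaluation.
* **Sensor errors** — static gyro bias (drawn U(−2, 2) deg/s per axis per
  participant), white gyro noise (0.5 deg/s), gyro bias random walk
  (0.05 deg/s/√s), accel white noise (0.02 g), per-axis accel gain/bias
  errors, and an optional band-limited (~0–5 Hz) translational artifact.
  These magnitudes are engineering choices for a consumer MEMS part; no
  manufacturer spec is assumed.

What the generator does **not** model: translational kinematics of gait
(accelerations are synthesized directly, not from body motion), soft-tissue
and mounting compliance, magnetic disturbance (no magnetometer exists in
the pipeline), temperature-dependent bias, and sampling jitter. Passing the
benchmarks therefore shows that the pipeline is correct and
well-conditioned under controlled conditions, not that the trained
classifiers transfer to real recordings.

## Feature schemes

The full scheme applies 30 statistics to each of the 6 raw channels and to
the two vector-sum series (accel ΣA², gyro Σω), plus one time-window
feature = elapsed seconds (with no timestamps, (n−1)/fs): 241 values. The
light scheme is max/min/range/variance/SD of the two vector-sum series: 10
values. Variance/SD use the sample (n−1) convention. Statistics that are
conventionally under-specified are pinned (and recorded in
`features.PINNED_DEFINITIONS`): Shannon entropy of a 16-bin histogram,
trapezoidal integration, lag-1 autocorrelation, Pearson correlation with
the 1-sample lag, 1 s moving-window means for the "moving" family,
mean |z-score|, coefficient of variation (0 at zero mean), strict
sign-change counts, and triplet-context definitions for the vector norm
and signal-magnitude-area. No normalization is applied to raw data.

## Head-pose filters

* **Complementary** — per-axis blend: tilt = β_c·(gyro-integrated) +
  (1−β_c)·(accel tilt); yaw is pure gyro integration. Operates in the Euler
  domain.
* **Mahony** — quaternion PI correction: e = a×v̂ (measured vs predicted
  gravity), ω_corr = ω + K_p·e + ∫K_I·e dt.
* **Madgwick** — q̇ = ½q⊗(0,ω) − β_m·∇f/‖∇f‖ with f the gravity-alignment
  residual.
* **Indirect EKF** — 9-dim error state [δθ, b_g, b_a]; nominal attitude
  propagated by bias-corrected gyro; first-order covariance transition
  Φ = [[I−[ωdt]×, −I dt, 0], [0, I, 0], [0, 0, I]]; measurement h = v̂ + b_a
  with H = [[v̂]×, 0, I]; Joseph-form update with explicit symmetrization;
  the attitude error is folded multiplicatively into the quaternion after
  each update. Four tunable noise densities (gyro noise, gyro-bias walk,
  accel noise, accel-bias walk) plus a 9×9 initial covariance
  (default diag([0.1 rad]³, [1 deg/s]³, [0.05 g]³)²).

All filters skip the accelerometer correction when ‖a‖ ∉ [0.5, 1.5] g
(free-fall/impact guard), initialize roll/pitch from the first second's
mean accelerometer with yaw = 0, and are pure functions of (trace, params).
Gravity cannot observe yaw, so the exactly-zero-measurement-noise limit of
the EKF is ill-conditioned; the noiseless-data checks use well-conditioned
default densities instead.

**Tuning** is exhaustive grid search minimizing the average of the azimuth
(yaw) and elevation (pitch) MAEs against a reference orientation — either
simulator ground truth or the calibration program (accel tilt averaged with
gyro-integrated tilt; yaw from the gyro integral). The out-of-the-box
defaults are always evaluated alongside the grid, so tuning can never
return something worse than the untuned filter. The standard noisy
benchmark (`filters.standard_noisy_benchmark`) is one 40° azimuth sweep and
one 30° elevation sweep, 12 s each, with per-seed random gyro bias and a
small seated-wearer translational artifact (0.02 g).

## Classifiers and training

FastRNN/FastGRNN/TCN consume raw (T, 6) windows; Bonsai/ProtoNN consume the
10-dim light features through an input standardizer fit on the training
set and stored with the model (the cited tree/prototype formulations
assume standardized features; raw features span five orders of magnitude).
Training minimizes cross-entropy — multiclass Crammer–Singer hinge for
Bonsai — with Adam (learning rates 0.001 TCN, 0.01 FastRNN/FastGRNN/Bonsai,
0.03 ProtoNN; step decay ×0.1 every 200 steps for the recurrent cells),
per-matrix L2 regularization for Bonsai (10⁻⁴ on Z, 10⁻³ on W/V/T) and
ProtoNN (5·10⁻⁶ on W, 5·10⁻⁵ on Z), and iterative hard thresholding after
a dense warm half of training (Bonsai nonzero densities Z/W/V/T =
0.2/0.3/0.3/0.62; ProtoNN W = 0.8). Bonsai trains with soft path
indicators (steep sigmoids of the branching responses) and predicts with
hard sign routing. FastGRNN's ζ, ν are trainable scalars initialized to
(1.0, 0.0). All training is a pure function of (seed, config). The
gradient engine is a small in-package reverse-mode autodiff over numpy
with an iterative topological-sort backward pass (BPTT graphs exceed the
recursion limit).

The recurrent models accept an integer `downsample` that decimates the
input window before the recurrence; the bundled studies use 4 (25 Hz
effective) — at 5 s windows this is 125 recurrent steps, which keeps
back-propagation through time tractable while retaining the gait band
(the generator's signal content lies below ~6 Hz).

## Resource model and search

Flash = nonzero parameters × 4 bytes (1 when quantized) + 2 kB schema
overhead; SRAM = max over layers of (input + activation elements) × element
size + 4 kB interpreter overhead; latency proxy = FLOPS with 1 MAC = 2
FLOPs. All three constants are configurable knobs — real toolchains differ
by an interpreter-dependent offset, which is exactly what the mock HIL
backend emulates (configurable flash/SRAM overheads; latency
a·FLOPS + b + noise). Within budget, the flash and SRAM objectives are
negative utilizations (the composite rewards filling the device); a budget
violation contributes +∞, which the GP surrogate absorbs as a finite
penalty cap (worst finite value + 3 ranges) to stay well-posed.

The search draws a fresh scalarization λ ~ Dirichlet(1,1,1,1) each
iteration and re-scalarizes the full observation history under it before
refitting the GP (Matérn-5/2 with per-dimension length scales, normalized
targets). Acquisition is UCB with β = 4 over 512 Monte-Carlo candidates
(encoded: ordinals scaled to [0,1], categoricals one-hot); evaluated
configs are never re-suggested, and small finite spaces are exhausted
exactly — which is what makes the brute-force equivalence check possible.
The incumbent is tracked under the reference weight (the λ-domain mean)
over feasible evaluations only, and is non-increasing by construction.
Batch suggestion: constant-liar (posterior-mean hallucination) or k-means
over the encoded top-acquisition candidates. The TCN space follows the
design-space table: 2–64 filters, kernel 2–16, 3–8 layers, dilations from
{1,…,256} constrained non-decreasing (unused layer slots canonicalized
to 1), residual on/off.

## Studies and problem sizes

The bundled benchmarks use a 10-participant synthetic dataset (9 classes ×
25 s each, 100 Hz; 3 690 five-second windows at 0.5 s stride), 3-fold
leave-one-participant-out splits with a 90:10 train:validation split
inside the retained participants, FastGRNN with 32 hidden units trained
for 10 epochs, ProtoNN/Bonsai for 40/30 epochs, and 2-fold × 3-seed
averaging for the window-size study at {1, 2, 3, 5} s. DTW separability
follows the snapshot protocol: 10 random 400-sample accel vector-sum
snapshots per class, mean pairwise DTW within and across classes. These
sizes make the whole verification surface run in minutes on one CPU while
leaving the measured effects (accuracy bars, orderings, trends) far from
their thresholds.

## Known limitations

* Yaw is unobservable from gravity alone; all filters drift in azimuth at
  the residual gyro-z bias rate. The tuned-filter comparisons measure each
  filter under this shared limitation.
* The DTW separability "diagonal < off-diagonal" property is an aggregate
  statement; the Tl/Tr pair is indistinguishable in accel vector sums by
  construction (squaring erases the turn direction).
* The quantization flag affects only the flash proxy (symmetric 8-bit
  storage); inference still runs in float.
* The mock HIL backend models overheads and latency linearly; real
  interpreter behavior (operator fusion, memory planning) is richer.
* Bonsai's soft-vs-hard routing can disagree near branching boundaries;
  scores are exact only where routing is confident.
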