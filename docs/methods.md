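# Methods

## The estimation problem

Surface EMG records the electrical activity of contracting muscle from skin
electrodes.  During coordinated arm movement, eight muscles acting on the
shoulder and elbow (biceps, triceps, anterior/middle/posterior deltoid,
pectoralis major, trapezius, teres major) produce amplitude-modulated,
approximately super-Gaussian signals that are linearly mixed at the
electrodes by volume conduction.  `emgkin` decodes four joint angles —
SAA, SFE, SPS (shoulder) and EFE (elbow), in degrees — continuously from
these eight channels, and evaluates whether one fixed decoder survives both
continued repetitions within a recording session and the non-stationarity
between two sessions.

## Synthetic sessions

No laboratory recordings ship with the package; a generator produces paired
EMG/kinematics sessions with the statistical structure the pipeline relies
on.  Its defaults define the package's reference conditions:

* **Protocol** — 15 repetitions per session, ~2 s each, separated by 3 s
  rests; two sessions; EMG at 1 kHz, motion at 50 Hz.
* **Motion templates** — minimum-jerk rest→peak→rest profiles per DoF.
  Four motion identities (M1–M4: hand-to-mouth, hand-to-shoulder, sagittal
  and coronal arm raises) differ in amplitude/sign pattern over
  (SAA, SFE, SPS, EFE).  Per-DoF peak-time fractions differ within each
  motion so the four angle profiles are linearly independent, giving the
  muscle drive an effective rank of about four (hence 3–5 principal
  components at the 95% threshold, as for real coordinated movement).
  Per-repetition amplitude jitter is uniform within ±10% (bounded at ±15%)
  and duration jitter ±10%, emulating free, self-paced repetition.
  Template amplitudes are free parameters of the model; the defaults span
  realistic ranges of motion (e.g. 150° shoulder flexion for the sagittal
  raise, 120° elbow flexion for hand-to-shoulder).
* **Muscle activations** — rectified linear drive
  `a_m(t) = max(0, Σ_j G[m,j]·d_j(t)) + tonic`, where `d` stacks angle
  deviations from the initial posture (deg) and angular velocities (deg/s).
  Muscles form agonist/antagonist pairs per DoF (±0.014/deg) with a small
  velocity term (±0.0012 s/deg, giving concentric/eccentric asymmetry) and
  a weak cross-DoF coupling (±0.004/deg).  The tonic offset defaults to 0,
  so rest intervals carry baseline noise only.  Activations are computed at
  the motion rate and upsampled to 1 kHz by linear interpolation.
* **EMG synthesis** — each muscle's source is its activation multiplying a
  unit-variance Gaussian carrier band-limited to 10–400 Hz; amplitude
  modulation makes active segments super-Gaussian (positive excess
  kurtosis) while rest segments are Gaussian baseline.  Channels are a
  diagonally dominant nonnegative crosstalk mixture (diagonal 1.0,
  off-diagonal decaying 0.12/0.05/0.02 with channel separation; row
  off-diagonal sum 0.40) plus white Gaussian baseline noise
  (sd 0.05, versus source amplitudes of order one — "moderate noise").
* **Inter-session drift** — session 2 multiplies each channel by a fixed
  factor in [0.85, 1.15].  Test–retest studies of surface-EMG amplitude
  across electrode re-applications report day-to-day changes of roughly
  10–30%, so ±8–15% represents a mild but realistic between-session change.
  Drift is per-channel gain only: no spectral change, no electrode-shift
  remixing, no fatigue.

What the generator does **not** emulate: motor-unit discharge structure,
EMG spectral compression under fatigue, within-session electrode drift,
subject-to-subject heterogeneity, or motion-capture soft-tissue artifact.
Passing tests therefore demonstrate the pipeline's correctness and its
robustness to the modelled non-stationarity, not performance on real
recordings.

## Conditioning

Both filters are Butterworth designs applied forward–backward
(zero-phase), since processing is offline and group delay would misalign
EMG with motion: an order-6 band-pass (three poles per edge) at 10–400 Hz
for EMG, an order-2 low-pass at 6 Hz for angles.  The two-pass application
squares the magnitude response, so effective stopband attenuation doubles
in dB while the passband stays flat within ±1 dB over 30–300 Hz.

## Decomposition

PCA is fitted on training EMG only: channel means, eigen-decomposition of
the sample covariance (ddof = 1), eigenvector signs fixed so each
component's largest-magnitude channel weight is positive, and
`k = min{k : cumulative eigenvalue fraction ≥ 0.95}` (components with
non-positive eigenvalues are never retained).  ICA runs on the whitened
components — whitening divides by the square roots of the PCA eigenvalues,
so ICA is purely a rotation of the PCA subspace — using the fixed-point
negentropy iteration with the log-cosh contrast (a = 1) and symmetric
decorrelation, tolerance 1e-6, at most 200 sweeps.  Log-cosh is the robust
default contrast for super-Gaussian sources such as active EMG; symmetric
decorrelation avoids the order-dependent error accumulation of deflation.

Two ambiguities require conventions.  ICA components are returned ordered
by the variance they explain when back-projected into channel space, with
each component's sign chosen so its largest-magnitude channel loading is
positive — any fixed convention works; this one is deterministic and
scale-free.  Second, identifiability: for Gaussian sources the independent
rotation is undetermined, and finite-sample fixed points may still satisfy
the convergence test.  The model therefore carries an `identifiable` flag,
set to false when no component's mean log-cosh contrast deviates from the
Gaussian expectation (E[log cosh ν] ≈ 0.37457) by more than five standard
errors.

Both models are strictly frozen after fitting: test-time projection and
unmixing use the stored means, projection, whitening scales and unmixing
matrix, and the test suite asserts via checksums that prediction never
updates them.

## Features and scaling

MAV (mean of |x|) is computed per component in 40-sample windows with
20-sample hop; each frame is stamped with its window-**end** time, keeping
the feature causal for online use.  At 1 kHz the 50 Hz frame rate matches
the motion rate by construction; frames pair with the motion sample nearest
the window-end time (mismatch ≤ half a motion period), and unpaired
overhang at either end is dropped.  Features are z-scored and targets
min–max scaled to [0, 1] per DoF, both fitted on training rows only;
Levenberg–Marquardt is scale-sensitive and the tanh/linear network works
best with order-one inputs and outputs.  Test-time angles outside the
training range simply map outside [0, 1].

## Network and training

Architecture (k, 5, 5, 5, 4) for the single multi-output network (sMLP) or
four (k, 5, 5, 5, 1) networks (mMLPs); tanh hidden units, linear output.
Weights and biases initialize uniformly in ±1/√fan_in from a seeded
generator; mMLPs offset the seed per DoF so the four initializations
differ.  Training is full-batch Levenberg–Marquardt on the sum-of-squares
loss with the exact Jacobian obtained by back-propagation — with ≤ ~200
parameters and 10³–10⁴ frames the damped normal equations
`(JᵀJ + λI)δ = −Jᵀr` are cheap to solve directly.  λ starts at 1e-3,
shrinks ×0.1 after an accepted step and grows ×10 after a rejected one
(accepted losses therefore decrease strictly); training stops at 200
epochs, at gradient infinity-norm < 1e-7, at loss < 1e-10, or when damping
is exhausted (λ ≥ 1e12, a stationary point to working precision).  There is
no validation-based early stopping: the parameter budget is small relative
to the data and the stopping rules are fixed across all experiments.

## Validation protocols

* **Intra-session**: leave-p-out with the *chronologically last* p = 7 of
  15 repetitions held out (8 train / 7 test).  Holding out the tail rather
  than a random subset probes estimation in continued movement repetitions,
  which is the deployment-relevant direction of generalization; a seeded
  random split is available for sensitivity checks.
* **Inter-session**: all 15 repetitions of session 1 train, all 15 of
  session 2 test — the probe of between-session non-stationarity.
* **Short/middle-term**: the test frames are split at floor(F/2) (odd frame
  to the second half); scoring each half separately exposes accuracy drift
  over the test duration.  The split is by frames of the concatenated test
  data, not by repetitions, so the halves have equal duration.
* Rest-gap frames are retained in training and scoring: the decoder must
  hold the posture through rest as well as track movement.  Each rest gap
  is attributed to the repetition preceding it, so a blocked split cuts the
  session at a single time point.

The score is the pooled R²: residual and total sums of squares are pooled
over all DoFs and frames before forming the ratio.  This weights DoFs by
their variance (a low-amplitude DoF cannot dominate the index) and is the
same index applied to the x, y, z coordinates for trajectory scoring.  It
can be negative; it is 1 exactly for perfect estimates and 0 exactly for
the per-DoF mean predictor.

## Forward kinematics

Torso-fixed frame at the shoulder center: x lateral (right), y anterior,
z up; the arm hangs along −z in the reference pose.  Shoulder rotation is
the intrinsic sequence SAA about y, SFE about x, SPS about the humerus long
axis; the elbow adds EFE about the humerus-fixed x axis.  With upper-arm
and forearm lengths L1 = 0.30 m and L2 = 0.27 m (anthropometrically
plausible defaults, configurable) the wrist-center position is

    p = R_sh·[0, 0, −L1]ᵀ + R_sh·R_x(EFE)·[0, 0, −L2]ᵀ.

Published joint-coordinate conventions differ in axis ordering; since the
chain is only used to map measured and estimated angle series through the
*same* geometry, any fixed, documented convention yields a valid
trajectory-level comparison.  Wrist and hand DoFs are fixed.

## Numerical choices and degenerate inputs

* Pooled R² refuses zero-variance measured data rather than returning a
  conventional value.
* `scale_targets` raises, naming the DoF, if a target is constant on the
  training rows; the input z-scorer maps constant feature columns to zero
  instead (a constant feature is harmless to the network).
* Rank-deficient covariance: PCA retains only positive-eigenvalue
  components; whitening refuses non-positive eigenvalues.
* ICA non-convergence returns the best iterate with `converged=False` and
  a warning; non-identifiability is flagged separately (see above).
* A singular LM system is handled by raising λ and retrying.
* Determinism: every stochastic step (jitter draws, noise, ICA and network
  initialization) derives from explicit integer seeds; identical
  configuration and seeds give bit-identical sessions, models and reports.

## Problem sizes

Default sessions are ~75 s (3,700+ motion samples, ~75,000 EMG samples per
channel).  The repeated-seed properties in the test suite (decoding
accuracy medians, ICA recovery) use 20 seeds; the blind-source-recovery
check uses 60 s of 1 kHz data per seed.  These sizes make all statistics
stable while keeping a full test run to a few minutes on one CPU.

## Known limitations

* The generator's EMG model is phenomenological (modulated filtered noise),
  not physiological; conclusions transfer to real EMG only to the extent
  that amplitude modulation plus linear mixing captures it.
* Inter-session non-stationarity is limited to static per-channel gain;
  real electrode shift also remixes sources, which would stress the frozen
  ICA harder than any gain change.
* The decoder is memoryless frame-to-frame (no temporal model); smoothness
  of the output comes entirely from the smoothness of the features.
* Min–max target scaling ties the output range to the training sessions'
  range of motion; movements far outside it extrapolate.
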