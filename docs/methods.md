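# Methods

This note documents the models behind `footimu`: the analysis pipeline's
procedure and numerical choices, the physics of the synthetic gait
generator, its default parameters, and what testing against synthetic
sessions does and does not demonstrate.

## The measurement model

A shoe is approximated as a rigid body over most of the gait cycle. All
sensors mounted on it then share the angular velocity **ω**, and the
acceleration at a sensor offset by the lever arm **r** (foot frame: x
forward, y left, z up; world frame z-up with gravity g = 9.81 m/s²) is

    a = a_s + α × r + ω × (ω × r),      specific force f = a − g,

where a_s is the acceleration of the foot origin and α the angular
acceleration. The Euler term α × r is included even though it is often
dropped in back-of-envelope estimates: without it the formula is not
consistent with the second time derivative of the mounted point's world
trajectory, which is exactly the consistency check the tests enforce
(finite-difference oracle, relative error < 1e−4). The centrifugal term is
written ω × (ω × r); for planar rotation it points outward. For the
reference case ω = 8.5 rad/s, |r| = 0.1 m its magnitude is
ω²r = 7.225 m/s².

Position-dependent deviations from the rigid signal are modeled as:

* **Impact transients** — each initial contact excites the attachment,
  modeled as an underdamped second-order oscillator with impulse response
  `exp(−ζω_n t)·sin(ω_d t)`, `ω_d = ω_n√(1−ζ²)`, added to acceleration and
  (scaled) angular velocity. The transient direction and amplitude jitter
  ±30 % per stride: the path of the pressure wave from heel to sensor is
  not repeatable, which is why attachment problems inflate per-stride
  variability far more than the mean error.
* **Continuous micro-vibration** — a loose clip never settles completely;
  white excitation shaped by the same oscillator, with an envelope that
  grows with the foot's angular speed (factor 1 + 1.5·‖ω‖ per rad/s).
  Its stance-phase floor is what the residual-energy feature E_vmin
  detects.
* **Rollover coupling** — sensors near the toe box see the late-stance
  shoe deformation as a delayed (15 ms) blend of their pitch channel,
  delaying their motion onset after foot-flat. This produces a
  *systematic* stride-length bias for the instep sensor (~2 cm under the
  defaults), unlike the zero-mean impact effects.

## Synthetic gait generator

One stride of duration T runs: border (minimum of the medial-lateral
gyroscope) → terminal contact (4 % of T) → swing with the forward
translation in [14 %, 60 %] and a 0.12 m foot lift → initial contact
(56 %) → foot-flat [62 %, 96 %] → next border. All angle and displacement
profiles are built from 9th-order (C⁴) smoothstep transitions between
plateaus, so velocity and angular velocity are *exactly* zero during
foot-flat — the ZUPT assumption holds by construction and the planar
displacement between consecutive foot-flat anchors defines the true stride
length. The C⁴ smoothness matters numerically: profiles with jerk
discontinuities leak spectral energy above the IMU Nyquist frequency and
contaminate the rigid-motion conservation checks with sampling artifacts
that have nothing to do with the modeled error pathways.

The simulation runs at 2048 Hz internally and is *point-sampled* at
204.8 Hz without an anti-alias filter, deliberately preserving the
under-sampling pathway of real hardware: energy that the attachment
oscillators place above ~102 Hz folds back into the passband and corrupts
the integration. Accelerometers clip at ±157 m/s² (±16 g), gyroscopes at
±2000 deg/s; white noise defaults to σ = 0.02 m/s² and 0.1 deg/s. Markers
(CAL at the heel, TOE at the shoe tip, 25 cm apart) are sampled at 100 Hz
with optional tracking gaps — run lengths both below and above the 80 ms
interpolability threshold — and a uniform ±10 ms IMU↔mocap clock offset
recorded in the session metadata, standing in for the hardware
synchronization of a real recording.

Default study conditions (chosen once as representative of healthy
adults): stride length/time of 1.05 m/1.25 s (slow), 1.30 m/1.10 s
(normal), 1.55 m/0.95 s (fast), with per-stride jitter of 3 cm and 20 ms;
the protocol mirrors a seven-test session (three 4×10 m and three 2×20 m
bouts at the three speeds, plus a longer free walk with 45° turning
strides), desk-scaled to 12 strides per test by default and 50 for the
error-structure analyses (300 labeled strides). Turning strides change
heading during swing with alternating direction.

Default mounting table (lever arm; f_n, ζ; impact gain; vibration gain;
rollover coupling):

| position | r [m] | f_n [Hz] | ζ | impact | vibration | rollover |
|----------|-------------------|-----|------|------|-------|-----|
| cavity | (0.05, 0, 0.02) | 120 | 0.70 | 0.25 | 0.006 | 0 |
| insole | (0.08, 0, 0.03) | 120 | 0.70 | 0.35 | 0.014 | 0.1 |
| instep | (0.10, 0, 0.07) | 60 | 0.40 | 0.08 | 0.030 | 0.8 |
| heel | (−0.05, 0, 0.06) | 50 | 0.12 | 1.00 | 0.060 | 0 |
| lateral | (−0.03, −0.04, 0.05) | 55 | 0.15 | 0.90 | 0.050 | 0 |
| medial | (−0.03, 0.04, 0.05) | 45 | 0.18 | 0.95 | 0.055 | 0 |

The table encodes the qualitative structure of the six attachments — stiff
embedded sensors, loose collar clips, a shielded but rollover-coupled
instep — and was calibrated so that the documented qualitative orderings
(E_vmin, MAE, high-band PSD, speed growth) emerge reproducibly; only
orderings, never magnitudes, are asserted in tests. Mounting rotations
default to distinct yaws with small tilts so the alignment step is
exercised nontrivially.

## Pipeline numerics

* **Static window**: first 500-sample window (sliding by 1) in which every
  accelerometer axis of every sensor has variance < 0.01 (m/s²)². The
  printed threshold is dimensionally ambiguous in common usage; it is
  implemented as a variance and configurable.
* **Yaw alignment**: the angle uses the *signed* 2D cross product in
  `atan2` — an unsigned angle cannot determine the rotation direction —
  and the median over retained samples (‖ω_xy‖ ≥ 150 deg/s in both
  sensors) for robustness against shoe deformation.
* **Orientation strapdown**: per-sample quaternion exponential with
  trapezoidal body-rate averaging plus the two-sample coning correction.
  Rectangular stepping leaves a systematic tilt error that leaks gravity
  into the horizontal and biased stride length by ≈1 cm at 204.8 Hz.
* **Dedrifting**: the logistic weight `w(t) = σ(c·(t−T/2)/T)` with c = 10
  is rescaled to reach exactly 0 and 1 at the stride ends, so the
  zero-velocity boundary conditions hold exactly rather than to within
  `σ(−c/2) ≈ 0.7 %`. Quadrature is trapezoidal throughout.
* **Events**: TC = first negative→positive zero crossing of the ML gyro;
  IC = most prominent negative ML-gyro peak in the last 55 % of the
  stride, refined to the adjacent superior-inferior acceleration minimum
  (±5 samples); t_vmin = center of the 8-sample (40 ms) window of minimal
  gyro-norm energy in [IC, end). These operators are this package's
  concrete realization of the usual heel-strike/toe-off/mid-stance
  detectors; all search fractions and window sizes are config keys.
* **Markers**: gaps ≤ 80 ms linearly interpolated; stride bounds mapped
  from the IMU clock via the session's clock offset and marker positions
  linearly interpolated at the bound instants; a bound inside an unfilled
  gap makes the stride unusable.
* **Statistics**: quantiles use linear interpolation (type 7); the
  cross-sensor standard deviation uses the n−1 denominator; Spearman
  correlation is reported because only rank-order claims are made.
* **Degenerate inputs**: strides shorter than the 64-sample Welch segment
  are flagged rather than padded; residual-energy windows truncated by the
  signal edge are flagged; a median static acceleration below 1 m/s²
  aborts orientation initialization with a structured error.

## What the synthetic tests show — and what they cannot

Passing tests demonstrate internal consistency: the integration recovers
known displacements from exactly-rigid signals (< 1 mm cross-sensor
spread, < 5 mm truth error at default sampling), the alignment recovers
known mounting yaws to fractions of a degree, the selection rules remove
exactly the constructed turning strides, and the attachment model
reproduces the qualitative position orderings. The generator emulates the
*statistical structure* real multi-sensor sessions are assumed to have —
not their full physics. It contains no joint-level biomechanics, no
ground-reaction forces, no soft-tissue artifact, no nonlinear or
amplitude-dependent attachment response, no gyroscope bias drift or
temperature effects, and marker noise is absent (gaps aside). Absolute
error magnitudes on synthetic sessions therefore say little about absolute
accuracy on real recordings; the supported claims are the directional and
structural ones. The left and right foot are generated independently:
inter-foot asymmetry is not modeled.

Known limitations: the t_vmin energy minimum on noise-free data sits at
the start of the flat phase rather than its center (any zero-energy window
ties; the first wins by the documented tie-break); the instep rollover
bias is deterministic where a real shoe would vary; and the free-walk test
approximates the figure-eight path as straight diagonals joined by
constant-angle turning strides.
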