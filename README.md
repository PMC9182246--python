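# footimu

Stride-length estimation from foot-mounted inertial sensors depends not
only on the algorithm but on *where and how* the sensor is attached to the
shoe. `footimu` is a library and command-line tool for quantifying that
dependence: it implements a complete multi-position gait-analysis
pipeline — sensor-to-sensor alignment, gait-event detection,
zero-velocity-update (ZUPT) anchored double integration, marker-based
reference comparison, and raw-signal features — for sessions in which six
synchronized IMUs per foot (insole, cavity, instep, heel, lateral, medial)
record the same strides, together with a rigid-body gait simulator that
generates such sessions with known ground truth.

It is aimed at researchers developing or validating shoe-worn IMU systems
who need to understand how attachment stiffness, lever arms, impact
transients and finite sampling rates propagate into spatial gait
parameters.

## Method

For a shoe treated as a rigid body, every mounted sensor measures the same
angular velocity **ω**, while the measured specific force at a point
offset by a lever arm **r** from the foot origin differs by the rigid-body
terms

    a = a_s + α × r + ω × (ω × r) − g,

the Euler and centrifugal accelerations. On top of this shared motion,
each attachment acts like a damped second-order oscillator (natural
frequency f_n, damping ratio ζ) excited by the heel-strike pressure wave,
which modulates the recorded signal in a position-dependent way.

The pipeline estimates stride length per *v_min stride* — the interval
between the instants of least movement (t_vmin) of two adjacent strides:

1. **Alignment**: gravity from a 500-sample static window maps each
   sensor's z-axis to vertical; the remaining yaw offset to the cavity
   sensor is the median over samples of the signed angle
   `atan2(ω_xy,i × ω_xy,j, ω_xy,i · ω_xy,j)`, keeping only samples with
   ‖ω_xy‖ ≥ 150 deg/s in both sensors.
2. **Events**: terminal contact, initial contact and t_vmin from the
   medial-lateral gyroscope within labeled strides; events out of order or
   with IC beyond 60 % of the cycle invalidate the stride.
3. **Integration**: initial orientation from the median acceleration in an
   8-sample window at t_vmin; quaternion strapdown integration of the
   gyroscope; gravity removal; forward–backward velocity integration with
   sigmoidal weighting so velocity is exactly zero at both stride ends;
   stride length = planar distance between start and end position.
4. **Reference and selection**: heel-marker (CAL) planar travel over the
   same interval is ground truth; strides where heel and toe references
   disagree by > 1 cm (turning strides) or any sensor's events failed are
   removed for all sensors.
5. **Statistics**: signed error (IMU − reference, positive =
   overestimation), MAE, IQR, Tukey and extreme (> 30 cm) outliers per
   sensor × speed category, and Spearman correlation of raw-signal
   features (E_vmin, a_max, Welch PSD band powers) with the error.

## Worked example

```bash
footimu simulate demo_session --seed 4 --strides-per-test 4 --free-walk-strides 4 --feet left
footimu all demo_session
```

The second command prints the per-category error summary (values in
meters; n is stride × sensor pairs after selection):

```
position  category  n  mean_error_m    mae_m    iqr_m  outliers  extreme_outliers
  cavity       all 19      0.000421 0.005854 0.005152         4                 0
  cavity      fast  6     -0.004241 0.009531 0.017745         0                 0
  cavity      slow  4     -0.000293 0.001372 0.001477         0                 0
    heel       all 19      0.004926 0.024629 0.046457         0                 0
    heel      fast  6      0.006174 0.036908 0.058151         0                 0
    heel      slow  4     -0.000312 0.020292 0.025945         0                 0
  ...
```

Reading: on this small synthetic session the cavity sensor (embedded in
the mid-sole, stiff attachment) reaches a mean absolute error of ~0.6 cm
against the heel-marker reference, while the heel-mounted clip — identical
rigid motion, but a low-damping attachment that rings after every heel
strike — is four times worse at ~2.5 cm, with a correspondingly wider IQR,
and both degrade from slow to fast walking. The mean errors of both stay
within a few millimeters of zero: averaging over strides hides attachment
problems that dominate single-stride accuracy. `demo_session/` also receives `stride_results.csv`,
`features.csv`, `pairwise_diffs.csv` and `exclusions.csv` with the
per-stride detail.

The same steps are available as library calls (`assemble_session`,
`run_pipeline`, `summarize_errors`) for programmatic use; see the module
docstrings.

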