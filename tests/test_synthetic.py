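"""Simulator: ground-truth kinematics, lever-arm physics, attachment
dynamics, sampling and session assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import footimu as fi
from footimu.synthetic import (
    INTERNAL_RATE,
    MountingSpec,
    PointKinematics,
    PoseSeries,
    apply_attachment_dynamics,
    default_mounts,
    generate_foot_pose,
    ideal_point_kinematics,
    oscillator_kernel,
    rigid_mounts,
    sample_imu,
    simulate_markers,
)


def _static_pose(n=2048, quat=None):
    """A pose standing perfectly still."""
    q = np.tile(quat if quat is not None else [0.0, 0.0, 0.0, 1.0], (n, 1))
    zeros = np.zeros((n, 3))
    return PoseSeries(
        fs=INTERNAL_RATE, t=np.arange(n) / INTERNAL_RATE, pos=zeros.copy(),
        quat=q, vel=zeros.copy(), acc=zeros.copy(), omega=zeros.copy(),
        alpha=zeros.copy(), strides=pd.DataFrame(), impacts=np.zeros((0, 2)),
    )


class TestGenerateFootPose:
    def test_true_length_matches_configuration(self):
        cfg = fi.GaitConfig(n_strides=1, stride_length_mean=1.3,
                            stride_length_std=0.0, stride_time_std=0.0)
        pose = generate_foot_pose(cfg)
        assert pose.strides.loc[0, "true_length_m"] == pytest.approx(1.3, abs=1e-4)

    def test_deterministic_given_seed(self):
        a = generate_foot_pose(fi.GaitConfig(n_strides=3, seed=7))
        b = generate_foot_pose(fi.GaitConfig(n_strides=3, seed=7))
        for field in ("pos", "quat", "vel", "acc", "omega", "alpha"):
            assert np.array_equal(getattr(a, field), getattr(b, field))
        assert a.strides.equals(b.strides)

    def test_every_stride_turns_when_fraction_is_one(self):
        cfg = fi.GaitConfig(n_strides=4, turn_fraction=1.0, turn_angle_deg=90.0, seed=2)
        pose = generate_foot_pose(cfg)
        for row in pose.strides.itertuples():
            q0 = Rotation.from_quat(pose.quat[row.istart])
            q1 = Rotation.from_quat(pose.quat[row.iend - 1])
            dyaw = np.degrees((q1 * q0.inv()).as_euler("ZYX")[0])
            assert dyaw == pytest.approx(row.turn_deg, abs=0.1)

    def test_foot_flat_intervals_exactly_static(self):
        pose = generate_foot_pose(fi.GaitConfig(n_strides=4, seed=11))
        for row in pose.strides.itertuples():
            i0, i1 = int(row.flat_start) * 10, int(row.flat_end) * 10
            assert np.all(pose.vel[i0:i1] == 0.0)
            assert np.all(pose.omega[i0:i1] == 0.0)

    def test_rejects_nonpositive_stride_parameters(self):
        with pytest.raises(ValueError):
            fi.GaitConfig(stride_length_mean=-1.0)
        with pytest.raises(ValueError):
            fi.GaitConfig(stride_time_mean=0.0)


class TestIdealPointKinematics:
    def test_planar_rotation_gives_centrifugal_magnitude(self):
        # constant spin of 8.5 rad/s with a 10 cm lever arm: the rotational
        # acceleration is w²r = 7.225 m/s², pointing inward along −r
        pose = _static_pose(256)
        pose.omega[:] = [0.0, 0.0, 8.5]
        mount = MountingSpec("cavity", r=(0.1, 0.0, 0.0))
        kin = ideal_point_kinematics(pose, mount)
        rot_acc = kin.acc - ideal_point_kinematics(pose, MountingSpec("cavity")).acc
        assert np.allclose(rot_acc, [-7.225, 0.0, 0.0], atol=1e-12)

    def test_zero_lever_arm_reproduces_origin_kinematics(self, rng):
        pose = generate_foot_pose(fi.GaitConfig(n_strides=2, seed=1))
        kin = ideal_point_kinematics(pose, MountingSpec("cavity", r=(0, 0, 0)))
        f_world = pose.acc - np.array([0, 0, -9.81])
        expect = Rotation.from_quat(pose.quat).apply(f_world, inverse=True)
        assert np.allclose(kin.acc, expect, atol=1e-12)

    def test_static_pose_measures_gravity_only(self):
        q = Rotation.from_euler("zy", [40, 25], degrees=True).as_quat()
        kin = ideal_point_kinematics(
            _static_pose(64, quat=q), MountingSpec.with_yaw("heel", yaw_deg=30, tilt_deg=10)
        )
        assert np.allclose(np.linalg.norm(kin.acc, axis=1), 9.81)
        assert np.allclose(kin.gyr, 0.0)

    def test_lever_arm_formula_matches_finite_differences(self):
        # independent oracle: second differences of the mounted point's
        # world trajectory must reproduce a_s + alpha×r + w×(w×r)
        pose = generate_foot_pose(fi.GaitConfig(n_strides=2, seed=3))
        mount = MountingSpec.with_yaw("heel", r=(-0.05, 0.03, 0.06), yaw_deg=30, tilt_deg=5)
        r_foot = Rotation.from_quat(pose.quat)
        p_mount = pose.pos + r_foot.apply(mount.r)
        dt = 1.0 / pose.fs
        a_fd = (p_mount[2:] - 2 * p_mount[1:-1] + p_mount[:-2]) / dt**2
        r_world = r_foot.apply(mount.r)
        a_ana = (
            pose.acc
            + np.cross(pose.alpha, r_world)
            + np.cross(pose.omega, np.cross(pose.omega, r_world))
        )
        err = np.linalg.norm(a_fd - a_ana[1:-1], axis=1).max()
        assert err / np.abs(a_ana).max() < 1e-4

    def test_mount_validation(self):
        with pytest.raises(ValueError):
            MountingSpec("heel", r=(0.3, 0.0, 0.0))
        with pytest.raises(ValueError):
            MountingSpec("heel", zeta=0.0)
        with pytest.raises(ValueError):
            MountingSpec("heel", rotation=np.array([1.0, 1.0, 0.0, 0.0]))


class TestAttachmentDynamics:
    def _impulse_setup(self, zeta, f_n=50.0, gain=1.0):
        n = 4096
        kin = PointKinematics(fs=INTERNAL_RATE, acc=np.zeros((n, 3)), gyr=np.zeros((n, 3)))
        mount = MountingSpec("heel", f_n=f_n, zeta=zeta, impact_gain=gain)
        impacts = np.array([[256.0, 1.0]])
        return apply_attachment_dynamics(kin, mount, impacts)

    def test_zero_gain_is_identity(self):
        pose = generate_foot_pose(fi.GaitConfig(n_strides=2, seed=4))
        kin = ideal_point_kinematics(pose, MountingSpec("cavity", r=(0.05, 0, 0.02)))
        out = apply_attachment_dynamics(
            kin, MountingSpec("cavity", impact_gain=0.0), pose.impacts
        )
        assert np.array_equal(out.acc, kin.acc)
        assert np.array_equal(out.gyr, kin.gyr)

    def test_transient_energy_decreases_with_damping(self):
        e = {}
        for zeta in (0.1, 0.9):
            out = self._impulse_setup(zeta)
            e[zeta] = float(np.sum(out.acc**2))
        assert e[0.1] > e[0.9]

    def test_impulse_response_oscillates_at_damped_frequency(self):
        # analytic second-order system: f_d = f_n * sqrt(1 - zeta²)
        f_n, zeta = 50.0, 0.2
        h = oscillator_kernel(f_n, zeta, INTERNAL_RATE)
        # zero crossings of exp(-a t)·sin(w_d t) sit exactly at k·pi/w_d
        sign_change = np.flatnonzero(np.sign(h[1:]) != np.sign(h[:-1]))
        spacing = np.diff(sign_change[:8]).mean() / INTERNAL_RATE
        f_d = 1.0 / (2.0 * spacing)
        assert f_d == pytest.approx(f_n * np.sqrt(1 - zeta**2), abs=0.5)

    def test_kernel_matches_closed_form(self):
        f_n, zeta = 40.0, 0.3
        h = oscillator_kernel(f_n, zeta, INTERNAL_RATE)
        t = np.arange(len(h)) / INTERNAL_RATE
        w_n = 2 * np.pi * f_n
        w_d = w_n * np.sqrt(1 - zeta**2)
        expect = np.exp(-zeta * w_n * t) * np.sin(w_d * t)
        expect /= np.abs(expect).max()
        assert np.max(np.abs(h - expect)) < 1e-6


class TestSampleImu:
    def test_constant_input_round_trips_without_noise(self):
        n = 1000
        kin = PointKinematics(
            fs=INTERNAL_RATE,
            acc=np.tile([1.0, -2.0, 9.81], (n, 1)),
            gyr=np.tile([0.1, 0.2, -0.3], (n, 1)),
        )
        st = sample_imu(kin, position="cavity", acc_noise=0.0, gyr_noise=0.0)
        assert np.allclose(st.acc, [1.0, -2.0, 9.81])
        assert np.allclose(st.gyr, np.degrees([0.1, 0.2, -0.3]))

    def test_supra_nyquist_component_aliases(self):
        # 120 Hz sampled at 204.8 Hz folds to 204.8 − 120 = 84.8 Hz
        n = 40960
        t = np.arange(n) / INTERNAL_RATE
        kin = PointKinematics(fs=INTERNAL_RATE, acc=np.zeros((n, 3)), gyr=np.zeros((n, 3)))
        kin.acc[:, 0] = np.sin(2 * np.pi * 120.0 * t)
        st = sample_imu(kin, position="cavity", acc_noise=0.0, gyr_noise=0.0)
        spec = np.abs(np.fft.rfft(st.acc[:, 0]))
        f_peak = np.fft.rfftfreq(st.n, 1 / 204.8)[np.argmax(spec)]
        assert f_peak == pytest.approx(84.8, abs=0.1)

    def test_range_clipping(self):
        n = 100
        kin = PointKinematics(
            fs=INTERNAL_RATE,
            acc=np.full((n, 3), 400.0),
            gyr=np.full((n, 3), np.radians(4000.0)),
        )
        st = sample_imu(kin, position="cavity", acc_noise=0.0, gyr_noise=0.0)
        assert np.all(st.acc == 157.0)
        assert np.all(st.gyr == 2000.0)

    def test_non_integer_decimation_rejected(self):
        kin = PointKinematics(fs=INTERNAL_RATE, acc=np.zeros((10, 3)), gyr=np.zeros((10, 3)))
        with pytest.raises(ValueError):
            sample_imu(kin, position="cavity", fs=300.0)


class TestSimulateMarkers:
    def test_static_pose_zero_offset_constant(self):
        pose = _static_pose(4096)
        out = simulate_markers(pose, {"CAL": (0.0, 0.0, 0.0)})
        assert np.allclose(out["CAL"].pos, 0.0)

    def test_straight_stride_markers_travel_equally(self):
        cfg = fi.GaitConfig(n_strides=1, stride_length_std=0.0, stride_time_std=0.0)
        pose = generate_foot_pose(cfg)
        out = simulate_markers(pose)
        row = pose.strides.iloc[0]
        d = {}
        for label, m in out.items():
            f0 = int(row.start / 204.8 * 100)
            f1 = int((row.flat_start + 5) / 204.8 * 100)
            d[label] = np.hypot(*(m.pos[f1, :2] - m.pos[f0, :2]))
        assert abs(d["CAL"] - d["TOE"]) < 1e-3

    def test_turning_stride_markers_disagree(self):
        cfg = fi.GaitConfig(n_strides=1, turn_fraction=1.0, turn_angle_deg=90.0,
                            stride_length_std=0.0, stride_time_std=0.0)
        pose = generate_foot_pose(cfg)
        out = simulate_markers(pose)
        row = pose.strides.iloc[0]
        d = {}
        for label, m in out.items():
            f0 = int(row.start / 204.8 * 100)
            f1 = int((row.flat_start + 5) / 204.8 * 100)
            d[label] = np.hypot(*(m.pos[f1, :2] - m.pos[f0, :2]))
        assert abs(d["CAL"] - d["TOE"]) > 0.01


class TestAssembleSession:
    def test_degenerate_mounts_give_identical_streams(self):
        proto = [fi.TestSpec("t", "normal", 3, 0.0)]
        ses = fi.assemble_session(
            proto, mounts=rigid_mounts(), seed=1, feet=("left",),
            noise=False, attachment=False,
        )
        ref = ses.sensors["left"]["cavity"]
        for pos in fi.POSITIONS:
            assert np.array_equal(ses.sensors["left"][pos].acc, ref.acc)
            assert np.array_equal(ses.sensors["left"][pos].gyr, ref.gyr)

    def test_deterministic_given_seed(self):
        proto = [fi.TestSpec("t", "normal", 3, 0.0)]
        a = fi.assemble_session(proto, seed=2, feet=("left",))
        b = fi.assemble_session(proto, seed=2, feet=("left",))
        for pos in fi.POSITIONS:
            assert np.array_equal(a.sensors["left"][pos].acc, b.sensors["left"][pos].acc)
        assert np.array_equal(a.markers["left"]["CAL"].gaps, b.markers["left"]["CAL"].gaps)
        assert a.strides["left"].df.equals(b.strides["left"].df)

    def test_speed_category_tags_recorded(self):
        proto = [fi.TestSpec(f"t_{s}", s, 2, 0.0) for s in ("slow", "normal", "fast")]
        ses = fi.assemble_session(proto, seed=1, feet=("left",))
        cats = ses.strides["left"].df.groupby("test_id")["speed_category"].first()
        assert cats["t_slow"] == "slow" and cats["t_fast"] == "fast"

    def test_duplicate_or_missing_positions_rejected(self):
        mounts = default_mounts()
        mounts.pop("medial")
        with pytest.raises(ValueError, match="medial|position"):
            fi.assemble_session(mounts=mounts, feet=("left",))

    def test_rigid_displacement_shared_by_sensors_and_markers(self, rigid_session):
        # pose-level conservation: over a straight stride every rigid point
        # travels the same planar distance; markers must agree to < 1 mm
        labels = rigid_session.strides["left"].df
        cal = rigid_session.markers["left"]["CAL"]
        toe = rigid_session.markers["left"]["TOE"]
        for row in labels.itertuples():
            f0 = int(row.flat_start / 204.8 * 100) + 1
            prev_flat = row.start  # borders sit in a zero-velocity span
            fp = int(prev_flat / 204.8 * 100)
            d_cal = np.hypot(*(cal.pos[f0, :2] - cal.pos[fp, :2]))
            d_toe = np.hypot(*(toe.pos[f0, :2] - toe.pos[fp, :2]))
            assert abs(d_cal - d_toe) < 1e-3
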