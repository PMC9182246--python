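"""Synthetic multi-sensor gait generator.

The generator produces ground-truth foot kinematics and simulates the six
shoe-mounted IMUs plus the heel/toe motion-capture markers with the
statistical structure the downstream analysis assumes:

* one rigid-body foot motion per foot that all sensors share — during each
  foot-flat interval velocity and angular velocity are *exactly* zero, so
  the zero-velocity assumption holds by construction and the planar
  displacement between consecutive foot-flat anchors defines the true
  stride length;
* position-dependent signal differences injected on top of the rigid
  motion: the lever arm of each mounting (Euler + centrifugal acceleration),
  a damped-oscillator transient excited at every initial ground contact
  (the attachment's frequency response), and a delayed rollover component
  for sensors coupled to the deforming toe box;
* sensor sampling at 204.8 Hz by deliberate point-sampling (no anti-alias
  filter) of a 2048 Hz internal simulation, preserving the aliasing error
  pathway of real hardware, plus white measurement noise and range clipping;
* marker trajectories at 100 Hz with optional tracking gaps and a small
  IMU↔mocap clock offset.

The kinematic profile of one stride is built from C⁴ smoothstep
transitions, so linear and angular acceleration are smooth and the
medial-lateral gyroscope trace carries the landmarks the event detectors
look for: a minimum at each stride border, a negative→positive zero
crossing at terminal contact, a dominant positive swing lobe, and a
prominent negative peak at initial contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .datatypes import (
    FEET,
    GRAVITY,
    IMU_RATE,
    MARKER_RATE,
    POSITIONS,
    ImuStream,
    MarkerStream,
    SensorSet,
    Session,
    StrideLabelList,
)

INTERNAL_RATE = 2048.0  # Hz, 10x the IMU rate

ACC_RANGE = 157.0  # m/s², ±16 g
GYR_RANGE = 2000.0  # deg/s

# stride phase layout, fractions of the stride time; the stride starts at
# the border minimum of the medial-lateral gyroscope
_DIP_HALF = 0.04       # half-width of the border dip
_SWING_PITCH_END = 0.50
_LAND_END = 0.62       # initial contact at the center (0.56) of the landing lobe
_TRANS_START = 0.14    # forward translation window
_TRANS_END = 0.60
_Z_MID = 0.37
_FLAT_START = 0.62     # exact zero-motion interval
_FLAT_END = 0.96
_IC_FRACTION = 0.56

_SPEED_PRESETS = {
    # speed category -> (stride length m, stride time s)
    "slow": (1.05, 1.25),
    "normal": (1.30, 1.10),
    "fast": (1.55, 0.95),
}

_MARKER_OFFSETS = {"CAL": (-0.09, 0.0, 0.02), "TOE": (0.16, 0.0, 0.02)}


# --------------------------------------------------------------------------
# smooth profile primitives


def _s2(u: np.ndarray) -> np.ndarray:
    """C⁴ smoothstep (9th order): derivatives 1–4 vanish at both ends.

    The high end-point smoothness keeps the spectral tails of the rigid
    motion steep (∝ f⁻⁶), so under-sampling artifacts in the simulated
    signals come from the modeled attachment transients, not from joints
    of the profile construction.
    """
    return u**5 * (126.0 + u * (-420.0 + u * (540.0 + u * (-315.0 + 70.0 * u))))


def _s2d(u: np.ndarray) -> np.ndarray:
    return 630.0 * (u * (1.0 - u)) ** 4


def _s2dd(u: np.ndarray) -> np.ndarray:
    return 2520.0 * (u * (1.0 - u)) ** 3 * (1.0 - 2.0 * u)


class _PiecewiseSmooth:
    """A scalar C⁴ trajectory: plateaus joined by smoothstep transitions.

    Transitions are non-overlapping ``(t0, t1, v0, v1)`` tuples sorted in
    time; the value between transitions is held constant, so first and
    second derivatives are exactly zero on every plateau.
    """

    def __init__(self, transitions: list[tuple[float, float, float, float]], v_init: float = 0.0):
        trans = sorted(transitions)
        for (a0, a1, _, av1), (b0, _, bv0, _) in zip(trans, trans[1:]):
            if b0 < a1 - 1e-12:
                raise ValueError(f"overlapping transitions at t={b0:.4f}")
            if not math.isclose(av1, bv0, abs_tol=1e-12):
                raise ValueError("discontinuous plateau values between transitions")
        self.t0 = np.array([tr[0] for tr in trans])
        self.t1 = np.array([tr[1] for tr in trans])
        self.v0 = np.array([tr[2] for tr in trans])
        self.v1 = np.array([tr[3] for tr in trans])
        self.v_init = v_init

    def eval(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return value, first and second time derivative at times ``t``."""
        val = np.full(t.shape, self.v_init, dtype=float)
        d1 = np.zeros_like(val)
        d2 = np.zeros_like(val)
        if len(self.t0) == 0:
            return val, d1, d2
        j = np.searchsorted(self.t0, t, side="right") - 1
        has = j >= 0
        jj = np.clip(j, 0, None)
        done = has & (t >= self.t1[jj])
        val[done] = self.v1[jj[done]]
        inside = has & ~done
        ji = jj[inside]
        w = self.t1[ji] - self.t0[ji]
        u = (t[inside] - self.t0[ji]) / w
        dv = self.v1[ji] - self.v0[ji]
        val[inside] = self.v0[ji] + dv * _s2(u)
        d1[inside] = dv * _s2d(u) / w
        d2[inside] = dv * _s2dd(u) / (w * w)
        return val, d1, d2


# --------------------------------------------------------------------------
# configuration types


@dataclass
class GaitConfig:
    """Parameters of one synthetic walking bout.

    Stride length and time are drawn per stride from normal distributions
    (``*_std`` may be zero for perfectly repeatable strides). A fraction
    ``turn_fraction`` of strides change heading by ``turn_angle_deg``
    during swing, alternating turn direction.
    """

    stride_length_mean: float = 1.30  # m
    stride_time_mean: float = 1.10  # s
    speed_category: str = "normal"
    n_strides: int = 20
    turn_fraction: float = 0.0
    turn_angle_deg: float = 90.0
    stride_length_std: float = 0.03  # m
    stride_time_std: float = 0.02  # s
    step_height_m: float = 0.12
    dip_deg: float = 4.0        # depth of the border minimum of the ML gyro
    swing_pitch_deg: float = 35.0
    lead_in_s: float = 3.0      # static standing before the first stride
    lead_out_s: float = 1.0
    seed: int = 0
    internal_fs: float = INTERNAL_RATE

    def __post_init__(self) -> None:
        if self.stride_length_mean <= 0 or self.stride_time_mean <= 0:
            raise ValueError("stride length and time must be positive")
        if not 0.0 <= self.turn_fraction <= 1.0:
            raise ValueError("turn_fraction must lie in [0, 1]")
        if self.n_strides < 1:
            raise ValueError("need at least one stride")
        if self.lead_in_s < 0.5 or self.lead_out_s < 0.3:
            raise ValueError("lead-in/lead-out too short for the phase layout")

    @classmethod
    def for_speed(cls, category: str, **overrides) -> "GaitConfig":
        length, time = _SPEED_PRESETS[category]
        kw = dict(stride_length_mean=length, stride_time_mean=time, speed_category=category)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class MountingSpec:
    """How one sensor is mounted on the shoe.

    ``r`` is the lever arm from the foot-segment origin to the sensor in
    the foot frame (x forward, y left, z up); ``rotation`` maps sensor-frame
    vectors into the foot frame. ``f_n`` and ``zeta`` are the natural
    frequency and damping ratio of the attachment treated as a second-order
    oscillator excited at each initial contact with amplitude scaled by
    ``impact_gain``; ``rollover_coupling`` is the fraction of the toe-pitch
    deformation (a delayed copy of the pitch motion) transmitted to the
    sensor.
    """

    position: str
    r: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    f_n: float = 80.0  # Hz
    zeta: float = 0.5
    impact_gain: float = 0.0
    rollover_coupling: float = 0.0
    vibration_gain: float = 0.0  # m/s² RMS of continuous attachment micro-vibration
    yaw_deg: float | None = None  # ground-truth z-rotation, kept for convenience

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if np.linalg.norm(self.r) > 0.2:
            raise ValueError("lever arm exceeds 0.2 m")
        if self.f_n <= 0 or self.zeta <= 0:
            raise ValueError("f_n and zeta must be positive")
        if not 0.0 <= self.rollover_coupling <= 1.0:
            raise ValueError("rollover_coupling must lie in [0, 1]")
        norm = np.linalg.norm(self.rotation)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("mounting rotation must be a unit quaternion")

    @classmethod
    def with_yaw(cls, position: str, *, yaw_deg: float = 0.0, tilt_deg: float = 0.0, **kw) -> "MountingSpec":
        rot = Rotation.from_euler("zy", [yaw_deg, tilt_deg], degrees=True)
        return cls(position=position, rotation=rot.as_quat(), yaw_deg=yaw_deg, **kw)


def default_mounts() -> dict[str, MountingSpec]:
    """Mounting table emulating the six shoe positions.

    Embedded sensors (cavity, insole) are stiff and well damped; the
    collar sensors (heel, lateral, medial) hang on flexible clips with low
    damping and strong impact response; the instep sensor sees little of
    the heel-strike pressure wave but most of the rollover deformation.
    """
    return {
        "cavity": MountingSpec.with_yaw("cavity", r=(0.05, 0.0, 0.02), yaw_deg=0.0,
                                        f_n=120.0, zeta=0.7, impact_gain=0.25,
                                        vibration_gain=0.006),
        "insole": MountingSpec.with_yaw("insole", r=(0.08, 0.0, 0.03), yaw_deg=5.0, tilt_deg=2.0,
                                        f_n=120.0, zeta=0.7, impact_gain=0.35,
                                        rollover_coupling=0.1, vibration_gain=0.014),
        "instep": MountingSpec.with_yaw("instep", r=(0.10, 0.0, 0.07), yaw_deg=120.0, tilt_deg=4.0,
                                        f_n=60.0, zeta=0.4, impact_gain=0.08,
                                        rollover_coupling=0.8, vibration_gain=0.030),
        "heel": MountingSpec.with_yaw("heel", r=(-0.05, 0.0, 0.06), yaw_deg=180.0, tilt_deg=5.0,
                                      f_n=50.0, zeta=0.12, impact_gain=1.0,
                                      vibration_gain=0.060),
        "lateral": MountingSpec.with_yaw("lateral", r=(-0.03, -0.04, 0.05), yaw_deg=-90.0, tilt_deg=5.0,
                                         f_n=55.0, zeta=0.15, impact_gain=0.9,
                                         vibration_gain=0.050),
        "medial": MountingSpec.with_yaw("medial", r=(-0.03, 0.04, 0.05), yaw_deg=90.0, tilt_deg=5.0,
                                        f_n=45.0, zeta=0.18, impact_gain=0.95,
                                        vibration_gain=0.055),
    }


def rigid_mounts() -> dict[str, MountingSpec]:
    """Degenerate table: zero lever arms, identity rotations, no dynamics."""
    return {p: MountingSpec.with_yaw(p, yaw_deg=0.0) for p in POSITIONS}


# --------------------------------------------------------------------------
# ground-truth pose


@dataclass
class PoseSeries:
    """Dense ground-truth kinematics of the foot-segment origin.

    World frame: z up, x the initial walking direction, ground plane x–y.
    ``quat`` is scalar-last (scipy convention) and maps foot-frame vectors
    into the world frame. ``acc`` is the linear acceleration of the origin
    (gravity not included), ``omega``/``alpha`` angular velocity and
    acceleration in the world frame. ``strides`` carries per-stride ground
    truth: borders on the IMU and internal clocks, the exact zero-motion
    (foot-flat) interval, the true planar stride length and straightness.
    ``impacts`` holds (internal sample, magnitude m/s) of each initial
    contact, exciting the attachment dynamics downstream.
    """

    fs: float
    t: np.ndarray
    pos: np.ndarray
    quat: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    strides: pd.DataFrame
    impacts: np.ndarray  # (M, 2): internal sample, magnitude

    @property
    def n(self) -> int:
        return self.t.shape[0]


def generate_foot_pose(config: GaitConfig) -> PoseSeries:
    """Generate one bout of ground-truth foot motion.

    Each stride runs border → terminal contact → swing → initial contact →
    foot-flat → border, with the forward translation confined to swing and
    exact zeros during foot-flat. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strides
    fs = config.internal_fs

    lengths = rng.normal(config.stride_length_mean, config.stride_length_std, n)
    lengths = np.clip(lengths, 0.2 * config.stride_length_mean, None)
    times = rng.normal(config.stride_time_mean, config.stride_time_std, n)
    times = np.clip(times, 0.5 * config.stride_time_mean, None)

    n_turn = int(round(config.turn_fraction * n))
    turn_deg = np.zeros(n)
    if n_turn > 0:
        idx = np.unique(np.round(np.linspace(0, n - 1, n_turn)).astype(int))
        signs = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0)
        turn_deg[idx] = config.turn_angle_deg * signs

    borders = config.lead_in_s + np.concatenate([[0.0], np.cumsum(times)])
    total = borders[-1] + config.lead_out_s
    n_samples = int(math.ceil(total * fs))
    n_samples += (-n_samples) % 10  # keep the IMU decimation grid exact
    t = np.arange(n_samples) / fs

    dip = math.radians(config.dip_deg)
    swing_pitch = math.radians(config.swing_pitch_deg)

    theta_tr: list[tuple[float, float, float, float]] = []
    psi_tr: list[tuple[float, float, float, float]] = []
    s_tr: list[tuple[float, float, float, float]] = []
    z_tr: list[tuple[float, float, float, float]] = []
    psi_acc = 0.0
    s_acc = 0.0
    for k in range(n):
        tk, T = borders[k], times[k]
        h = _DIP_HALF * (min(times[k - 1], T) if k else T)
        theta_tr.append((tk - h, tk + h, 0.0, -dip))
        theta_tr.append((tk + _DIP_HALF * T, tk + _SWING_PITCH_END * T, -dip, swing_pitch))
        theta_tr.append((tk + _SWING_PITCH_END * T, tk + _LAND_END * T, swing_pitch, 0.0))
        s_tr.append((tk + _TRANS_START * T, tk + _TRANS_END * T, s_acc, s_acc + lengths[k]))
        s_acc += lengths[k]
        z_tr.append((tk + _TRANS_START * T, tk + _Z_MID * T, 0.0, config.step_height_m))
        z_tr.append((tk + _Z_MID * T, tk + _TRANS_END * T, config.step_height_m, 0.0))
        if turn_deg[k] != 0.0:
            dpsi = math.radians(turn_deg[k])
            psi_tr.append((tk + _TRANS_START * T, tk + _TRANS_END * T, psi_acc, psi_acc + dpsi))
            psi_acc += dpsi
    # closing border minimum after the last stride, recovering to flat
    T = times[-1]
    h = _DIP_HALF * T
    t_end = borders[-1]
    theta_tr.append((t_end - h, t_end + h, 0.0, -dip))
    theta_tr.append((t_end + h, t_end + 3 * h, -dip, 0.0))

    theta, theta_d, theta_dd = _PiecewiseSmooth(theta_tr).eval(t)
    psi, psi_d, psi_dd = _PiecewiseSmooth(psi_tr).eval(t)
    s, s_d, s_dd = _PiecewiseSmooth(s_tr).eval(t)
    z, z_d, z_dd = _PiecewiseSmooth(z_tr).eval(t)

    cos_p, sin_p = np.cos(psi), np.sin(psi)
    vel = np.column_stack([s_d * cos_p, s_d * sin_p, z_d])
    acc = np.column_stack(
        [s_dd * cos_p - s_d * psi_d * sin_p, s_dd * sin_p + s_d * psi_d * cos_p, z_dd]
    )
    # planar position by high-rate trapezoidal integration of the exact velocity
    pos = np.zeros((n_samples, 3))
    dt = 1.0 / fs
    pos[1:, 0] = np.cumsum(0.5 * (vel[1:, 0] + vel[:-1, 0]) * dt)
    pos[1:, 1] = np.cumsum(0.5 * (vel[1:, 1] + vel[:-1, 1]) * dt)
    pos[:, 2] = z

    # orientation R = Rz(psi) @ Ry(theta); body-frame gyro y-component is theta_d
    quat = Rotation.from_euler("ZY", np.column_stack([psi, theta])).as_quat()
    omega = np.column_stack([-theta_d * sin_p, theta_d * cos_p, psi_d])
    alpha = np.column_stack(
        [
            -theta_dd * sin_p - theta_d * psi_d * cos_p,
            theta_dd * cos_p - theta_d * psi_d * sin_p,
            psi_dd,
        ]
    )

    imu_borders = np.round(borders * IMU_RATE).astype(int)
    int_borders = np.round(borders * fs).astype(int)
    rows = []
    for k in range(n):
        tk, T = borders[k], times[k]
        anchor = int(round((tk + 0.8 * T) * fs))
        start_i = int_borders[k]
        true_len = float(np.hypot(*(pos[anchor, :2] - pos[start_i, :2])))
        rows.append(
            {
                "stride_id": k,
                "start": int(imu_borders[k]),
                "end": int(imu_borders[k + 1]),
                "istart": int(start_i),
                "iend": int(int_borders[k + 1]),
                # padded one sample inward so the interval is exactly static
                # despite border rounding
                "flat_start": int(math.ceil((tk + _FLAT_START * T) * IMU_RATE)) + 1,
                "flat_end": int(math.floor((tk + _FLAT_END * T) * IMU_RATE)) - 1,
                "true_length_m": true_len,
                "turn_deg": float(turn_deg[k]),
                "straight": bool(turn_deg[k] == 0.0),
                "speed_category": config.speed_category,
            }
        )
    strides = pd.DataFrame(rows)

    swing_speed = 2.4609375 * np.hypot(  # peak of the C⁴ smoothstep rate
        lengths / (_TRANS_END - _TRANS_START), config.step_height_m / (_Z_MID - _TRANS_START)
    ) / times
    impact_samples = np.round((borders[:-1] + _IC_FRACTION * times) * fs).astype(int)
    impacts = np.column_stack([impact_samples, swing_speed])

    return PoseSeries(
        fs=fs, t=t, pos=pos, quat=quat, vel=vel, acc=acc, omega=omega, alpha=alpha,
        strides=strides, impacts=impacts,
    )


# --------------------------------------------------------------------------
# mounted-point kinematics and attachment dynamics


@dataclass
class PointKinematics:
    """Ideal sensor-frame signals at a mounted point: specific force in
    m/s² and angular velocity in rad/s, both before sampling and noise."""

    fs: float
    acc: np.ndarray
    gyr: np.ndarray

    def copy(self) -> "PointKinematics":
        return replace(self, acc=self.acc.copy(), gyr=self.gyr.copy())


def ideal_point_kinematics(pose: PoseSeries, mount: MountingSpec) -> PointKinematics:
    """Rigid-body signals at the mounted point, in the sensor frame.

    The acceleration of a point fixed on a rigid body offset by ``r`` from
    the origin is ``a = a_s + α×r + ω×(ω×r)`` (Euler + centrifugal terms,
    all in the world frame with ``r`` rotated accordingly). The sensor
    measures specific force, i.e. gravity ``g = (0, 0, −9.81)`` m/s² is
    subtracted, and both signals are expressed in the sensor frame via the
    foot orientation composed with the mounting rotation.
    """
    r_foot = Rotation.from_quat(pose.quat)
    r_world = r_foot.apply(mount.r)
    a_pt = (
        pose.acc
        + np.cross(pose.alpha, r_world)
        + np.cross(pose.omega, np.cross(pose.omega, r_world))
    )
    f_world = a_pt - np.array([0.0, 0.0, -GRAVITY])
    r_sensor = r_foot * Rotation.from_quat(mount.rotation)
    acc_s = r_sensor.apply(f_world, inverse=True)
    gyr_s = r_sensor.apply(pose.omega, inverse=True)
    return PointKinematics(fs=pose.fs, acc=acc_s, gyr=gyr_s)


def oscillator_kernel(f_n: float, zeta: float, fs: float) -> np.ndarray:
    """Peak-normalized impulse response of a second-order damped oscillator.

    ``h(t) = exp(−ζ ω_n t) · sin(ω_d t)`` with ``ω_d = ω_n √(1−ζ²)``,
    truncated once the envelope falls below 1e−4 of its peak.
    """
    if not 0.0 < zeta < 1.0:
        raise ValueError("only underdamped attachments are modeled (0 < zeta < 1)")
    w_n = 2.0 * math.pi * f_n
    w_d = w_n * math.sqrt(1.0 - zeta * zeta)
    t_max = -math.log(1e-4) / (zeta * w_n)
    t = np.arange(0.0, t_max, 1.0 / fs)
    h = np.exp(-zeta * w_n * t) * np.sin(w_d * t)
    return h / np.max(np.abs(h))

# direction (sensor frame) along which the impact transient acts, and the
# conversion gains from impact magnitude (m/s) to transient amplitude
_IMPACT_DIR_ACC = np.array([0.35, 0.20, 0.91574547])
_IMPACT_DIR_GYR = np.array([0.25, 0.88741591, 0.39])
_IMPACT_ACC_RATE = 8.0  # 1/s
_IMPACT_GYR_RATE = 1.0  # rad/m
_ROLLOVER_DELAY_S = 0.015
_VIBRATION_GYR_DPS_PER_MPS2 = 15.0  # gyro micro-vibration per unit acc vibration
_VIBRATION_SPEED_COUPLING = 1.5  # vibration envelope growth per rad/s of foot rotation


def apply_attachment_dynamics(
    kin: PointKinematics,
    mount: MountingSpec,
    impacts: np.ndarray,
    rng: np.random.Generator | None = None,
) -> PointKinematics:
    """Modulate ideal signals with the attachment's frequency response.

    Each initial contact excites the mounting oscillator; the response is
    added to the acceleration (and, scaled, to the angular velocity) along
    fixed sensor-frame directions with amplitude ``impact_gain × magnitude``.
    A nonzero ``vibration_gain`` adds continuous micro-vibration — white
    excitation shaped by the same oscillator — modeling the low-level
    wobble of a loose clip that never fully settles, even during stance
    (requires ``rng``). Sensors with nonzero ``rollover_coupling``
    additionally see the pitch channel blended toward a delayed copy of
    itself, delaying their motion onset around the rollover the way a
    deforming toe box does.
    """
    out = kin.copy()
    n = out.acc.shape[0]
    if mount.impact_gain > 0.0 and len(impacts):
        h = oscillator_kernel(mount.f_n, mount.zeta, kin.fs)
        for sample, mag in impacts:
            i = int(sample)
            if i >= n:
                continue
            if rng is None:
                d_acc, d_gyr = _IMPACT_DIR_ACC, _IMPACT_DIR_GYR
                scale = 1.0
            else:
                # the pressure-wave path varies stride to stride: random
                # transient direction and ±30% amplitude jitter
                d_acc = rng.standard_normal(3)
                d_acc /= np.linalg.norm(d_acc)
                d_gyr = rng.standard_normal(3)
                d_gyr /= np.linalg.norm(d_gyr)
                scale = 1.0 + 0.3 * float(rng.uniform(-1, 1))
            seg = slice(i, min(i + len(h), n))
            resp = h[: seg.stop - i] * (mount.impact_gain * mag * scale)
            out.acc[seg] += resp[:, None] * (d_acc * _IMPACT_ACC_RATE)
            out.gyr[seg] += resp[:, None] * (d_gyr * _IMPACT_GYR_RATE)
    if mount.vibration_gain > 0.0 and rng is not None:
        h = oscillator_kernel(mount.f_n, mount.zeta, kin.fs)
        h = h / math.sqrt(float(np.sum(h * h)))  # unit-energy shaping filter
        # wobble grows with movement intensity: quiet floor during stance,
        # stronger shaking while the foot swings
        envelope = 1.0 + _VIBRATION_SPEED_COUPLING * np.linalg.norm(kin.gyr, axis=1)
        for ax in range(3):
            shaped = envelope * np.convolve(rng.standard_normal(n), h, mode="same")
            out.acc[:, ax] += mount.vibration_gain * shaped
            shaped = envelope * np.convolve(rng.standard_normal(n), h, mode="same")
            out.gyr[:, ax] += (
                math.radians(_VIBRATION_GYR_DPS_PER_MPS2 * mount.vibration_gain) * shaped
            )
    c = mount.rollover_coupling
    if c > 0.0:
        d = int(round(_ROLLOVER_DELAY_S * kin.fs))
        if d > 0:
            delayed = np.concatenate([np.repeat(out.gyr[:1, 1], d), out.gyr[:-d, 1]])
            out.gyr[:, 1] = (1.0 - c) * out.gyr[:, 1] + c * delayed
            for ax in (0, 2):
                delayed = np.concatenate([np.repeat(out.acc[:1, ax], d), out.acc[:-d, ax]])
                out.acc[:, ax] = (1.0 - c) * out.acc[:, ax] + c * delayed
    return out


def sample_imu(
    kin: PointKinematics,
    *,
    position: str,
    foot: str = "left",
    fs: float = IMU_RATE,
    acc_noise: float = 0.02,
    gyr_noise: float = 0.1,
    rng: np.random.Generator | None = None,
) -> ImuStream:
    """Point-sample the dense signals at the IMU rate.

    No anti-alias filter is applied — energy above the output Nyquist
    frequency folds back, as it does in the modeled hardware. White noise
    (standard deviations in m/s² and deg/s) is added per channel, the
    gyroscope is converted to deg/s, and both channels are clipped to the
    sensor ranges (±157 m/s², ±2000 deg/s).
    """
    factor = kin.fs / fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"internal rate {kin.fs} is not an integer multiple of {fs}")
    step = int(round(factor))
    acc = kin.acc[::step].copy()
    gyr = np.degrees(kin.gyr[::step])
    if acc_noise > 0.0 or gyr_noise > 0.0:
        rng = rng if rng is not None else np.random.default_rng(0)
        acc += rng.normal(0.0, acc_noise, acc.shape)
        gyr += rng.normal(0.0, gyr_noise, gyr.shape)
    np.clip(acc, -ACC_RANGE, ACC_RANGE, out=acc)
    np.clip(gyr, -GYR_RANGE, GYR_RANGE, out=gyr)
    return ImuStream(position=position, foot=foot, fs=fs, acc=acc, gyr=gyr)


def simulate_markers(
    pose: PoseSeries,
    offsets: dict[str, tuple[float, float, float]] | None = None,
    *,
    fs: float = MARKER_RATE,
    clock_offset: float = 0.0,
    gap_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, MarkerStream]:
    """Sample marker world trajectories at the motion-capture rate.

    Mocap frame ``j`` corresponds to world time ``j/fs + clock_offset``.
    ``gap_rate`` (expected gaps per second) inserts tracking dropouts whose
    run lengths straddle the 80 ms interpolability threshold: short gaps
    (20–80 ms) and long ones (120–300 ms) both occur.
    """
    offsets = offsets if offsets is not None else _MARKER_OFFSETS
    r_foot = Rotation.from_quat(pose.quat)
    t_end = pose.t[-1]
    n_frames = int(math.floor((t_end - clock_offset) * fs)) + 1
    t_frames = np.arange(n_frames) / fs + clock_offset
    out: dict[str, MarkerStream] = {}
    for label, off in offsets.items():
        world = pose.pos + r_foot.apply(np.asarray(off, dtype=float))
        sampled = np.column_stack(
            [np.interp(t_frames, pose.t, world[:, ax]) for ax in range(3)]
        )
        gaps = np.zeros(n_frames, dtype=bool)
        if gap_rate > 0.0:
            g = rng if rng is not None else np.random.default_rng(0)
            for _ in range(g.poisson(gap_rate * (t_end - pose.t[0]))):
                if g.random() < 0.7:
                    run = int(g.integers(2, 9))  # 20–80 ms
                else:
                    run = int(g.integers(12, 31))  # 120–300 ms
                start = int(g.integers(0, max(n_frames - run, 1)))
                gaps[start : start + run] = True
            sampled[gaps] = np.nan
        out[label] = MarkerStream(label=label, fs=fs, pos=sampled, gaps=gaps)
    return out


# --------------------------------------------------------------------------
# session assembly


@dataclass
class TestSpec:
    """One gait test of the recording protocol."""

    test_id: str
    speed_category: str = "normal"
    n_strides: int = 12
    turn_fraction: float = 0.0
    turn_angle_deg: float = 90.0


def default_protocol(n_per_speed_test: int = 12, n_free_walk: int = 40) -> list[TestSpec]:
    """The seven-test protocol: 4×10 m and 2×20 m bouts at three
    self-selected speeds plus a longer free figure-eight walk, with turn
    strides interleaved at the segment ends."""
    tests = []
    for course, turn_frac in (("4x10", 0.25), ("2x20", 0.12)):
        for speed in ("slow", "normal", "fast"):
            tests.append(
                TestSpec(
                    test_id=f"{course}_{speed}",
                    speed_category=speed,
                    n_strides=n_per_speed_test,
                    turn_fraction=turn_frac,
                )
            )
    tests.append(
        TestSpec(test_id="5min", speed_category="normal", n_strides=n_free_walk,
                 turn_fraction=0.3, turn_angle_deg=45.0)
    )
    return tests


def _chain_pose(pose: PoseSeries, yaw: float, origin: np.ndarray) -> PoseSeries:
    """Rotate a bout about z by ``yaw`` and translate it to ``origin`` so
    consecutive gait tests join without kinematic discontinuities."""
    rot = Rotation.from_euler("z", yaw)
    pos = rot.apply(pose.pos)
    pos[:, :2] += origin[:2]
    return replace(
        pose,
        pos=pos,
        vel=rot.apply(pose.vel),
        acc=rot.apply(pose.acc),
        omega=rot.apply(pose.omega),
        alpha=rot.apply(pose.alpha),
        quat=(rot * Rotation.from_quat(pose.quat)).as_quat(),
        strides=pose.strides.copy(),
        impacts=pose.impacts.copy(),
    )


def _concat_poses(poses: list[PoseSeries]) -> PoseSeries:
    fs = poses[0].fs
    offsets_int = np.cumsum([0] + [p.n for p in poses[:-1]])
    stride_frames = []
    impact_parts = []
    sid = 0
    for p, off in zip(poses, offsets_int):
        df = p.strides.copy()
        off_imu = off // 10
        for col in ("start", "end", "flat_start", "flat_end"):
            df[col] += off_imu
        for col in ("istart", "iend"):
            df[col] += off
        df["stride_id"] = np.arange(sid, sid + len(df))
        sid += len(df)
        stride_frames.append(df)
        imp = p.impacts.copy()
        if len(imp):
            imp[:, 0] += off
        impact_parts.append(imp)
    n_total = sum(p.n for p in poses)
    return PoseSeries(
        fs=fs,
        t=np.arange(n_total) / fs,
        pos=np.concatenate([p.pos for p in poses]),
        quat=np.concatenate([p.quat for p in poses]),
        vel=np.concatenate([p.vel for p in poses]),
        acc=np.concatenate([p.acc for p in poses]),
        omega=np.concatenate([p.omega for p in poses]),
        alpha=np.concatenate([p.alpha for p in poses]),
        strides=pd.concat(stride_frames, ignore_index=True),
        impacts=np.concatenate(impact_parts) if impact_parts else np.zeros((0, 2)),
    )


def _pose_end_yaw(pose: PoseSeries) -> float:
    return float(Rotation.from_quat(pose.quat[-1]).as_euler("ZYX")[0])


def assemble_session(
    protocol: list[TestSpec] | None = None,
    mounts: dict[str, MountingSpec] | None = None,
    *,
    seed: int = 0,
    feet: tuple[str, ...] = FEET,
    noise: bool = True,
    attachment: bool = True,
    marker_gaps: bool = True,
    clock_jitter: bool = True,
    gait_overrides: dict | None = None,
) -> Session:
    """Build a complete synthetic session.

    All six sensors of a foot derive from one :class:`PoseSeries` per foot
    (common rigid motion); the gait tests of the protocol are chained into
    one continuous recording per foot with static standing phases between
    them (those breaks split the stride list into gait sequences). The
    ground-truth stride table, the mounting table and the IMU↔mocap clock
    offset are recorded in ``session.meta``. Deterministic given ``seed``.
    """
    protocol = protocol if protocol is not None else default_protocol()
    mounts = mounts if mounts is not None else default_mounts()
    if sorted(mounts) != sorted(POSITIONS):
        raise ValueError(
            f"need exactly one MountingSpec per position {POSITIONS}, got {sorted(mounts)}"
        )
    root = np.random.SeedSequence(seed)
    foot_seeds = {foot: sq for foot, sq in zip(feet, root.spawn(len(feet)))}
    misc_rng = np.random.default_rng(root.spawn(1)[0])
    clock_offset = float(misc_rng.uniform(-0.01, 0.01)) if clock_jitter else 0.0

    sensors: dict[str, SensorSet] = {}
    markers: dict[str, dict[str, MarkerStream]] = {}
    stride_tables: dict[str, StrideLabelList] = {}
    tests_meta: dict[str, list[dict]] = {}

    for foot in feet:
        sq = foot_seeds[foot]
        test_seeds = sq.spawn(len(protocol) + 2)
        poses = []
        yaw, origin = 0.0, np.zeros(3)
        meta_rows = []
        sample_off = 0
        for spec, child in zip(protocol, test_seeds[: len(protocol)]):
            cfg_kw = dict(
                n_strides=spec.n_strides,
                turn_fraction=spec.turn_fraction,
                turn_angle_deg=spec.turn_angle_deg,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            cfg_kw.update(gait_overrides or {})
            cfg = GaitConfig.for_speed(spec.speed_category, **cfg_kw)
            pose = _chain_pose(generate_foot_pose(cfg), yaw, origin)
            poses.append(pose)
            yaw = _pose_end_yaw(pose)
            origin = pose.pos[-1]
            meta_rows.append(
                {
                    "test_id": spec.test_id,
                    "speed_category": spec.speed_category,
                    "start": sample_off // 10,
                    "end": (sample_off + pose.n) // 10,
                }
            )
            sample_off += pose.n
        pose = _concat_poses(poses)
        strides = pose.strides
        strides["test_id"] = np.repeat(
            [row["test_id"] for row in meta_rows], [len(p.strides) for p in poses]
        )
        strides["stride_id"] = [f"{foot[0].upper()}{i:04d}" for i in range(len(strides))]
        tests_meta[foot] = meta_rows

        imu_rng = np.random.default_rng(test_seeds[-2].generate_state(1)[0] % (2**31))
        streams = {}
        for position in POSITIONS:
            mount = mounts[position]
            kin = ideal_point_kinematics(pose, mount)
            if attachment:
                kin = apply_attachment_dynamics(kin, mount, pose.impacts, rng=imu_rng)
            streams[position] = sample_imu(
                kin,
                position=position,
                foot=foot,
                acc_noise=0.02 if noise else 0.0,
                gyr_noise=0.1 if noise else 0.0,
                rng=imu_rng,
            )
        sensors[foot] = SensorSet(foot=foot, streams=streams)

        marker_rng = np.random.default_rng(test_seeds[-1].generate_state(1)[0] % (2**31))
        markers[foot] = simulate_markers(
            pose,
            clock_offset=clock_offset,
            gap_rate=0.03 if marker_gaps else 0.0,
            rng=marker_rng,
        )
        stride_tables[foot] = StrideLabelList(
            strides.drop(columns=["istart", "iend"])
        )

    meta = {
        "imu_fs": IMU_RATE,
        "marker_fs": MARKER_RATE,
        "marker_clock_offset_s": clock_offset,
        "seed": seed,
        "mounts": {
            p: {
                "r": list(map(float, m.r)),
                "rotation": list(map(float, m.rotation)),
                "f_n": m.f_n,
                "zeta": m.zeta,
                "impact_gain": m.impact_gain,
                "rollover_coupling": m.rollover_coupling,
                "yaw_deg": m.yaw_deg,
            }
            for p, m in mounts.items()
        },
        "tests": tests_meta,
    }
    return Session(sensors=sensors, markers=markers, strides=stride_tables, meta=meta)
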