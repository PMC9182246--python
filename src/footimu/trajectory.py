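"""Per-stride strapdown double integration → IMU stride length.

Over one v_min stride (t_vmin to t_vmin of the adjacent stride) the sensor
is stationary at both ends, which anchors the integration:

1. *Initial orientation*: in an 8-sample (40 ms) window centered on the
   starting t_vmin the only acceleration is gravity, so the rotation
   mapping the median in-window accelerometer vector onto the world +z
   axis levels the sensor; the free heading is fixed by rotating the
   sensor x-axis's ground-plane projection onto the forward direction
   (1, 0, 0). Stride length is a planar norm, so this heading convention
   does not affect it.
2. *Orientation integration*: per-sample quaternion-exponent steps of the
   gyroscope (the sampling rate is high relative to the signal bandwidth).
3. *Gravity removal*: acceleration rotated to the world frame minus
   (0, 0, 9.81) m/s².
4. *Dedrifted velocity*: the forward cumulative integral (v(start)=0) and
   the backward integral (v(end)=0) are blended with a sigmoidal weight,
   forcing zero velocity at both stride ends — the zero-velocity update —
   while distributing the accumulated drift smoothly over the stride.
5. *Position*: trapezoidal integration of the velocity; the stride length
   is the Euclidean distance between start and end point in the ground
   plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .datatypes import GRAVITY, ImuStream
from .events import VminStride

INIT_WINDOW_SAMPLES = 8
SIGMOID_STEEPNESS = 10.0


class TrajectoryError(RuntimeError):
    pass


@dataclass
class StrideTrajectory:
    """Integration products over one v_min stride (world frame)."""

    quat: np.ndarray      # (N, 4) scalar-last orientation
    acc_world: np.ndarray  # (N, 3) gravity-free linear acceleration, m/s²
    vel: np.ndarray        # (N, 3) dedrifted velocity, m/s
    pos: np.ndarray        # (N, 3) position, m

    @property
    def stride_length(self) -> float:
        return float(np.hypot(*(self.pos[-1, :2] - self.pos[0, :2])))


def initial_orientation(
    stream: ImuStream,
    tvmin: int,
    window: int = INIT_WINDOW_SAMPLES,
) -> Rotation:
    """Orientation (sensor→world) at the start of a v_min stride."""
    a = max(tvmin - window // 2, 0)
    b = min(tvmin + window - window // 2, stream.n)
    med = np.median(stream.acc[a:b], axis=0)
    norm = np.linalg.norm(med)
    if norm < 1.0:
        raise TrajectoryError(
            f"degenerate static window at sample {tvmin}: median acc norm {norm:.3f}"
        )
    v = med / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    if s < 1e-12:
        tilt = Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0, 0])
    else:
        tilt = Rotation.from_rotvec(axis / s * np.arctan2(s, c))
    # remaining heading: project the leveled sensor x-axis to the ground
    # plane and rotate it onto (1, 0, 0) with the shortest z-rotation
    x_world = tilt.apply([1.0, 0.0, 0.0])
    heading = np.arctan2(x_world[1], x_world[0])
    return Rotation.from_euler("z", -heading) * tilt


def integrate_orientation(gyr_dps: np.ndarray, q0: Rotation, fs: float) -> np.ndarray:
    """Propagate the orientation through per-sample body rates.

    ``q_{k+1} = q_k ∘ exp(ω_k Δt)`` with renormalization each step; returns
    scalar-last quaternions, one per input sample.
    """
    omega = np.radians(gyr_dps)
    dt = 1.0 / fs
    # trapezoidal body-rate average plus the classic two-sample coning
    # correction: second-order accurate and free of the systematic tilt
    # drift of the rectangular rule
    rotvec = np.empty_like(omega)
    rotvec[:-1] = 0.5 * (omega[:-1] + omega[1:]) * dt + (dt * dt / 12.0) * np.cross(
        omega[:-1], omega[1:]
    )
    rotvec[-1] = omega[-1] * dt  # unused (no step after the last sample)
    half = 0.5 * rotvec
    angle = np.linalg.norm(half, axis=1)
    # quaternion exponential, series-safe near zero angle
    small = angle < 1e-8
    k = np.empty_like(angle)
    k[small] = 1.0 - angle[small] ** 2 / 6.0
    k[~small] = np.sin(angle[~small]) / angle[~small]
    dq = np.empty((len(omega), 4))
    dq[:, :3] = half * k[:, None]
    dq[:, 3] = np.cos(angle)

    out = np.empty((len(omega), 4))
    q = q0.as_quat()
    out[0] = q
    for i in range(len(omega) - 1):
        x1, y1, z1, w1 = q
        x2, y2, z2, w2 = dq[i]
        q = np.array(
            [
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            ]
        )
        q /= np.linalg.norm(q)
        out[i + 1] = q
    return out


def dedrifted_velocity(
    acc_world: np.ndarray,
    fs: float,
    steepness: float = SIGMOID_STEEPNESS,
) -> np.ndarray:
    """Forward–backward integrated velocity with sigmoidal blending.

    ``v = (1−w)·v_fwd + w·v_bwd`` where ``v_fwd`` assumes v=0 at the start,
    ``v_bwd`` assumes v=0 at the end, and the logistic weight
    ``w(t) = σ(c·(t−T/2)/T)`` is rescaled to reach exactly 0 and 1 at the
    stride endpoints, so both boundary conditions hold exactly.
    """
    n = acc_world.shape[0]
    v_fwd = cumulative_trapezoid(acc_world, dx=1.0 / fs, axis=0, initial=0.0)
    drift = v_fwd[-1]
    tau = np.linspace(0.0, 1.0, n)
    w = 1.0 / (1.0 + np.exp(-steepness * (tau - 0.5)))
    w = (w - w[0]) / (w[-1] - w[0])
    return v_fwd - w[:, None] * drift


def stride_trajectory(
    stream: ImuStream,
    vmin: VminStride,
    *,
    init_window: int = INIT_WINDOW_SAMPLES,
    steepness: float = SIGMOID_STEEPNESS,
    gravity: float = GRAVITY,
) -> StrideTrajectory:
    """Full double integration of one v_min stride of an aligned stream."""
    seg = stream.segment(vmin.start, vmin.end)
    if seg.n < init_window:
        raise TrajectoryError("v_min stride shorter than the initialization window")
    q0 = initial_orientation(stream, vmin.start, init_window)
    quat = integrate_orientation(seg.gyr, q0, stream.fs)
    acc_world = Rotation.from_quat(quat).apply(seg.acc)
    acc_world[:, 2] -= gravity
    vel = dedrifted_velocity(acc_world, stream.fs, steepness)
    pos = cumulative_trapezoid(vel, dx=1.0 / stream.fs, axis=0, initial=0.0)
    return StrideTrajectory(quat=quat, acc_world=acc_world, vel=vel, pos=pos)


def stride_length(stream: ImuStream, vmin: VminStride, **kw) -> float:
    """Planar distance traveled by the sensor over one v_min stride, m."""
    return stride_trajectory(stream, vmin, **kw).stride_length
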