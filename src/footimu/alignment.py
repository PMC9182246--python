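"""Orientation alignment of all sensors of one foot to the cavity sensor.

Because the shoe is approximately rigid, every sensor on it measures the
same angular velocity up to the (unknown) relative orientation of the
sensor housings. The alignment runs in two steps:

1. *Gravity alignment* — during an initial standing phase the only
   measured acceleration is gravity; the shortest rotation mapping the
   median accelerometer vector of a static window onto the local +z axis
   removes the tilt of each sensor, leaving only a rotation about z
   undetermined.
2. *Yaw alignment* — per sample, the signed angle between the horizontal
   angular-velocity vectors of a sensor and the reference follows from
   ``atan2(ω_xy,i × ω_xy,j, ω_xy,i · ω_xy,j)`` (2D cross product in the
   numerator, so the direction of rotation is resolved). Samples where
   either sensor's ‖ω_xy‖ falls below a threshold are dominated by noise
   and discarded; the median of the retained angles is the yaw offset.

The cavity sensor serves as the common reference: its orientation is fixed
by the cavity machined into the mid-sole, so it is only gravity-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .datatypes import ImuStream, SensorSet

#: defaults of the procedure
STATIC_WINDOW_SAMPLES = 500
STATIC_VAR_THRESHOLD = 0.01  # (m/s²)², per accelerometer axis
YAW_OMEGA_THRESHOLD_DPS = 150.0


class AlignmentError(RuntimeError):
    """Raised when a session lacks the content the procedure needs."""


@dataclass
class SensorAlignment:
    gravity_rotation: np.ndarray  # unit quaternion (scalar-last)
    yaw_rad: float
    n_samples_used: int


@dataclass
class AlignmentResult:
    static_window: tuple[int, int]
    per_sensor: dict[str, SensorAlignment]


def _sliding_variance(x: np.ndarray, window: int) -> np.ndarray:
    """Population variance of every length-``window`` sliding window,
    computed from cumulative sums (one value per start index)."""
    c1 = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x, dtype=float)])
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    return np.maximum(s2 / window - (s1 / window) ** 2, 0.0)


def find_static_window(
    sensor_set: SensorSet,
    window: int = STATIC_WINDOW_SAMPLES,
    var_threshold: float = STATIC_VAR_THRESHOLD,
) -> tuple[int, int]:
    """First window in which every sensor is static.

    Slides a window of ``window`` samples one sample at a time and returns
    the first ``[start, start + window)`` where the variance of each
    accelerometer axis of *every* sensor of the set is below the threshold
    simultaneously.
    """
    if sensor_set.n < window:
        raise AlignmentError(f"recording shorter than the {window}-sample static window")
    ok = None
    for position in sensor_set:
        acc = sensor_set[position].acc
        sensor_ok = np.ones(sensor_set.n - window + 1, dtype=bool)
        for ax in range(3):
            sensor_ok &= _sliding_variance(acc[:, ax], window) < var_threshold
        ok = sensor_ok if ok is None else (ok & sensor_ok)
    starts = np.flatnonzero(ok)
    if not len(starts):
        raise AlignmentError("no static region")
    start = int(starts[0])
    return start, start + window


def _shortest_rotation_to_z(vec: np.ndarray) -> Rotation:
    """Shortest rotation mapping ``vec`` onto +z (handles the antipodal case)."""
    v = vec / np.linalg.norm(vec)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])  # any axis ⊥ z works
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle)


def gravity_align(stream: ImuStream, window: tuple[int, int]) -> tuple[ImuStream, Rotation]:
    """Rotate a stream so the median static acceleration points along +z."""
    start, end = window
    if start < 0 or end > stream.n:
        raise AlignmentError("static window outside the stream")
    med = np.median(stream.acc[start:end], axis=0)
    if np.linalg.norm(med) < 1.0:
        raise AlignmentError(
            f"no usable gravity vector in static window of {stream.position} "
            f"(median norm {np.linalg.norm(med):.3f} m/s²)"
        )
    rot = _shortest_rotation_to_z(med)
    out = stream.copy()
    out.acc = rot.apply(out.acc)
    out.gyr = rot.apply(out.gyr)
    return out, rot


def yaw_align(
    stream: ImuStream,
    reference: ImuStream,
    omega_threshold: float = YAW_OMEGA_THRESHOLD_DPS,
) -> tuple[float, int]:
    """Median signed yaw angle rotating ``stream`` onto ``reference``.

    Both streams must already be gravity-aligned and share a sample clock.
    Returns the angle in rad and the number of retained samples.
    """
    if stream.n != reference.n:
        raise AlignmentError("streams differ in length")
    wi = stream.gyr[:, :2]
    wj = reference.gyr[:, :2]
    keep = (np.linalg.norm(wi, axis=1) >= omega_threshold) & (
        np.linalg.norm(wj, axis=1) >= omega_threshold
    )
    if not keep.any():
        raise AlignmentError("insufficient dynamic content for yaw alignment")
    wi, wj = wi[keep], wj[keep]
    cross = wi[:, 0] * wj[:, 1] - wi[:, 1] * wj[:, 0]
    dot = np.einsum("ij,ij->i", wi, wj)
    angles = np.arctan2(cross, dot)
    return float(np.median(angles)), int(keep.sum())


def rotate_about_z(stream: ImuStream, angle: float) -> ImuStream:
    rot = Rotation.from_euler("z", angle)
    out = stream.copy()
    out.acc = rot.apply(out.acc)
    out.gyr = rot.apply(out.gyr)
    return out


def align_sensor_set(
    sensor_set: SensorSet,
    *,
    window: int = STATIC_WINDOW_SAMPLES,
    var_threshold: float = STATIC_VAR_THRESHOLD,
    omega_threshold: float = YAW_OMEGA_THRESHOLD_DPS,
    reference: str = "cavity",
) -> tuple[SensorSet, AlignmentResult]:
    """Gravity-align every stream, then yaw-align each to the reference.

    The reference sensor itself is only gravity-aligned (its yaw is 0 by
    definition). Alignment is usually run per gait test — pass per-test
    slices of the session for that.
    """
    static = find_static_window(sensor_set, window, var_threshold)
    leveled: dict[str, ImuStream] = {}
    rotations: dict[str, Rotation] = {}
    for position in sensor_set:
        leveled[position], rotations[position] = gravity_align(sensor_set[position], static)
    aligned: dict[str, ImuStream] = {}
    per_sensor: dict[str, SensorAlignment] = {}
    ref_stream = leveled[reference]
    for position in sensor_set:
        if position == reference:
            aligned[position] = leveled[position]
            yaw, n_used = 0.0, ref_stream.n
        else:
            yaw, n_used = yaw_align(leveled[position], ref_stream, omega_threshold)
            aligned[position] = rotate_about_z(leveled[position], yaw)
        per_sensor[position] = SensorAlignment(
            gravity_rotation=rotations[position].as_quat(),
            yaw_rad=yaw,
            n_samples_used=n_used,
        )
    return (
        SensorSet(foot=sensor_set.foot, streams=aligned),
        AlignmentResult(static_window=static, per_sensor=per_sensor),
    )
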