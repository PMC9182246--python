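"""Marker-based reference stride lengths and stride selection.

The heel (CAL) marker provides the accepted ground-truth stride length;
the toe (TOE) marker is computed alongside as a quality criterion: for a
straight stride every point of a rigid foot travels the same planar
distance, so a heel–toe disagreement beyond a small threshold flags a
turning stride (or a marker-tracking problem) and removes the stride from
the sensor comparison.

Marker trajectories arrive at 100 Hz with tracking gaps; gaps up to 80 ms
are linearly interpolated, longer ones stay missing. Stride bounds are
given on the IMU clock (204.8 Hz); the known IMU↔mocap clock offset maps
them to mocap time, and marker positions at the bound instants are
obtained by linear interpolation between the neighboring frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MarkerStream
from .events import VminStride

MARKER_MAX_GAP_MS = 80.0
STRAIGHTNESS_THRESHOLD_M = 0.01


def fill_marker_gaps(
    marker: MarkerStream, max_gap_ms: float = MARKER_MAX_GAP_MS
) -> MarkerStream:
    """Linearly interpolate tracking gaps not longer than ``max_gap_ms``.

    Longer gaps (and gaps touching the ends of the recording) remain
    missing and keep their gap flag.
    """
    out = marker.copy()
    max_run = int(round(max_gap_ms / 1000.0 * marker.fs))
    gaps = out.gaps
    if not gaps.any():
        return out
    # locate runs of consecutive gap frames
    padded = np.concatenate([[False], gaps, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for a, b in zip(starts, ends):
        run = b - a
        if run > max_run or a == 0 or b >= marker.n:
            continue
        left, right = a - 1, b  # valid neighbors
        frac = (np.arange(a, b) - left) / (right - left)
        out.pos[a:b] = out.pos[left] + frac[:, None] * (out.pos[right] - out.pos[left])
        out.gaps[a:b] = False
    return out


def _marker_at_time(marker: MarkerStream, t: float, clock_offset: float) -> np.ndarray | None:
    """Marker position at world time ``t`` by linear interpolation, or None
    when either bracketing frame is missing."""
    f = (t - clock_offset) * marker.fs
    i = int(np.floor(f))
    if i < 0 or i + 1 >= marker.n:
        return None
    if marker.gaps[i] or marker.gaps[i + 1]:
        return None
    frac = f - i
    return (1.0 - frac) * marker.pos[i] + frac * marker.pos[i + 1]


def reference_stride_length(
    marker: MarkerStream,
    vmin: VminStride,
    imu_fs: float,
    clock_offset: float = 0.0,
) -> float | None:
    """Planar distance the marker traveled over a v_min stride, m.

    Returns None when a stride bound falls into an unfilled gap or outside
    the marker recording (stride unusable).
    """
    p0 = _marker_at_time(marker, vmin.start / imu_fs, clock_offset)
    p1 = _marker_at_time(marker, vmin.end / imu_fs, clock_offset)
    if p0 is None or p1 is None:
        return None
    return float(np.hypot(*(p1 - p0)[:2]))


@dataclass
class ReferenceLength:
    stride_id: object
    position: str  # sensor whose v_min bounds were used
    heel: float | None
    toe: float | None


def reference_lengths(
    vmin_strides: list[VminStride],
    cal: MarkerStream,
    toe: MarkerStream,
    imu_fs: float,
    clock_offset: float = 0.0,
    max_gap_ms: float = MARKER_MAX_GAP_MS,
) -> list[ReferenceLength]:
    """Heel and toe reference lengths for every v_min stride of one sensor."""
    cal = fill_marker_gaps(cal, max_gap_ms)
    toe = fill_marker_gaps(toe, max_gap_ms)
    out = []
    for vm in vmin_strides:
        out.append(
            ReferenceLength(
                stride_id=vm.stride_id,
                position=vm.position,
                heel=reference_stride_length(cal, vm, imu_fs, clock_offset),
                toe=reference_stride_length(toe, vm, imu_fs, clock_offset),
            )
        )
    return out


def select_strides(
    refs_per_sensor: dict[str, list[ReferenceLength]],
    valid_ids_per_sensor: dict[str, set],
    threshold_m: float = STRAIGHTNESS_THRESHOLD_M,
) -> tuple[set, pd.DataFrame]:
    """Common stride set for a fair cross-sensor comparison.

    A stride id is kept iff for *every* sensor of the foot: the events were
    valid (a v_min stride exists), the marker data was usable at both
    bounds, and |heel − toe| ≤ ``threshold_m`` (straightness). A violation
    for one sensor removes the stride for all. Returns the kept ids and a
    table of per-stride exclusion reasons.
    """
    all_ids: set = set()
    for ids in valid_ids_per_sensor.values():
        all_ids |= ids
    for refs in refs_per_sensor.values():
        all_ids |= {r.stride_id for r in refs}

    reasons = []
    kept = set()
    refs_by_key = {
        (pos, r.stride_id): r for pos, refs in refs_per_sensor.items() for r in refs
    }
    positions = sorted(valid_ids_per_sensor)
    for sid in sorted(all_ids, key=str):
        reason = None
        for pos in positions:
            if sid not in valid_ids_per_sensor[pos]:
                reason = f"events_invalid:{pos}"
                break
            r = refs_by_key.get((pos, sid))
            if r is None or r.heel is None or r.toe is None:
                reason = f"marker_unusable:{pos}"
                break
            if abs(r.heel - r.toe) > threshold_m:
                reason = f"not_straight:{pos}"
                break
        if reason is None:
            kept.add(sid)
        else:
            reasons.append({"stride_id": sid, "excluded": True, "reason": reason})
    reason_df = pd.DataFrame(reasons, columns=["stride_id", "excluded", "reason"])
    return kept, reason_df
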