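"""Stride-border refinement, gait-event detection and v_min strides.

Strides are labeled on the medial-lateral (ML) gyroscope, whose trace over
one gait cycle shows a minimum at each stride border (just before the
terminal contact), a negative→positive zero crossing at toe-off, a large
positive lobe during swing and a prominent negative peak at the initial
contact. Within each labeled stride three events are detected per sensor:

* TC (terminal contact / toe-off): first negative→positive zero crossing
  of the ML gyroscope after the stride start;
* IC (initial contact / heel strike): the most prominent negative ML-gyro
  peak in the post-swing search region, refined to the adjacent minimum of
  the superior-inferior acceleration;
* t_vmin (least movement / mid-stance): the center of the 8-sample window
  with the smallest gyroscope-norm energy between IC and the stride end —
  the anchor for the zero-velocity update downstream.

From consecutive valid strides that share a border, *v_min strides* are
built running from the t_vmin of one stride to the t_vmin of the next, so
every integration interval starts and ends in a resting phase. Each gait
sequence therefore yields one v_min stride fewer than it has valid strides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .datatypes import ImuStream, StrideLabelList

SNAP_WINDOW_MS = 50.0
IC_SEARCH_FRACTION = 0.45  # IC search starts at this fraction of the stride
IC_REFINE_SAMPLES = 5      # half-width of the accelerometer refinement window
TVMIN_WINDOW_SAMPLES = 8   # 40 ms at 204.8 Hz
IC_VALID_FRACTION = 0.6    # IC must fall in the first 60% of the cycle

#: axis indices after alignment: y is medial-lateral, z superior-inferior
ML_AXIS = 1
SI_AXIS = 2


@dataclass
class StrideEvents:
    stride_id: object
    start: int
    end: int
    tc: int | None
    ic: int | None
    tvmin: int | None
    valid: bool
    reason: str  # "none", "order", "no_ic_60"


def snap_stride_borders(
    gyr_ml: np.ndarray,
    labels: StrideLabelList,
    fs: float,
    window_ms: float = SNAP_WINDOW_MS,
) -> StrideLabelList:
    """Move every stride border to the ML-gyro minimum in a ±window/2 range.

    Borders shared by adjacent strides are snapped once, so they remain
    shared afterwards. Borders whose search window would leave the signal
    are clamped to the valid range.
    """
    half = max(int(round(window_ms / 2000.0 * fs)), 1)
    df = labels.df.copy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    borders = np.unique(np.concatenate([starts, ends]))
    snapped = {}
    for b in borders:
        lo = max(int(b) - half, 0)
        hi = min(int(b) + half + 1, len(gyr_ml))
        snapped[int(b)] = lo + int(np.argmin(gyr_ml[lo:hi]))
    df["start"] = [snapped[int(b)] for b in starts]
    df["end"] = [snapped[int(b)] for b in ends]
    return StrideLabelList(df)


def detect_events(
    stream: ImuStream,
    start: int,
    end: int,
    stride_id=None,
    *,
    ic_search_fraction: float = IC_SEARCH_FRACTION,
    tvmin_window: int = TVMIN_WINDOW_SAMPLES,
) -> StrideEvents:
    """Detect TC, IC and t_vmin inside one labeled stride of an aligned stream."""
    ml = stream.gyr[start:end, ML_AXIS]
    n = end - start

    # TC: first zero crossing from negative to non-negative
    neg = ml[:-1] < 0
    crossing = np.flatnonzero(neg & (ml[1:] >= 0))
    tc = start + int(crossing[0]) + 1 if len(crossing) else None

    # IC: most prominent negative ML-gyro peak in the post-swing region,
    # refined to the adjacent superior-inferior acceleration minimum
    ic = None
    lo = int(np.floor(ic_search_fraction * n))
    seg = ml[lo:]
    if len(seg) >= 3:
        peaks, props = find_peaks(-seg, prominence=0.0)
        if len(peaks):
            best = peaks[int(np.argmax(props["prominences"]))]
            cand = start + lo + int(best)
            a = max(cand - IC_REFINE_SAMPLES, start)
            b = min(cand + IC_REFINE_SAMPLES + 1, end)
            ic = a + int(np.argmin(stream.acc[a:b, SI_AXIS]))

    # t_vmin: center of the minimum-energy gyroscope window in [ic, end)
    tvmin = None
    if ic is not None:
        energy = np.einsum("ij,ij->i", stream.gyr[ic:end], stream.gyr[ic:end])
        if len(energy) >= tvmin_window:
            windowed = np.convolve(energy, np.ones(tvmin_window), mode="valid")
            tvmin = ic + int(np.argmin(windowed)) + tvmin_window // 2

    ev = StrideEvents(
        stride_id=stride_id, start=start, end=end, tc=tc, ic=ic, tvmin=tvmin,
        valid=False, reason="none",
    )
    return validate_events(ev)


def validate_events(ev: StrideEvents) -> StrideEvents:
    """Flag event sets that are unusable for integration.

    Invalid when any event is missing or out of the order TC < IC < t_vmin
    (reason ``order``), or when the IC falls beyond the first 60% of the
    gait cycle (reason ``no_ic_60``).
    """
    if ev.tc is None or ev.ic is None or ev.tvmin is None:
        ev.valid, ev.reason = False, "order"
        return ev
    if not (ev.start <= ev.tc < ev.ic < ev.tvmin < ev.end):
        ev.valid, ev.reason = False, "order"
        return ev
    if (ev.ic - ev.start) > IC_VALID_FRACTION * (ev.end - ev.start):
        ev.valid, ev.reason = False, "no_ic_60"
        return ev
    ev.valid, ev.reason = True, "none"
    return ev


def detect_all_events(
    stream: ImuStream,
    labels: StrideLabelList,
    **kw,
) -> list[StrideEvents]:
    return [
        detect_events(stream, int(row.start), int(row.end), row.stride_id, **kw)
        for row in labels
    ]


@dataclass
class VminStride:
    stride_id: object  # inherited from the stride the start t_vmin belongs to
    start: int
    end: int
    position: str


def build_vmin_strides(
    events: list[StrideEvents],
    labels: StrideLabelList,
    position: str,
) -> list[VminStride]:
    """One v_min stride per adjacent pair of valid strides.

    Bounds run from the t_vmin of stride k to the t_vmin of stride k+1 and
    are therefore specific to the sensor the events came from.
    """
    by_id = {ev.stride_id: ev for ev in events}
    out = []
    rows = list(labels)
    for k, k1 in labels.adjacent_pairs():
        a = by_id.get(rows[k].stride_id)
        b = by_id.get(rows[k1].stride_id)
        if a is None or b is None or not (a.valid and b.valid):
            continue
        if a.tvmin is None or b.tvmin is None or a.tvmin >= b.tvmin:
            continue
        out.append(VminStride(stride_id=a.stride_id, start=a.tvmin, end=b.tvmin,
                              position=position))
    return out


def events_table(events: list[StrideEvents], position: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stride_id": [e.stride_id for e in events],
            "position": position,
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "tc": [e.tc for e in events],
            "ic": [e.ic for e in events],
            "tvmin": [e.tvmin for e in events],
            "valid": [e.valid for e in events],
            "reason": [e.reason for e in events],
        }
    )
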