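"""Raw-signal comparison metrics and per-stride features.

Two sample-wise similarity metrics compare sensor pairs over *labeled*
strides (identical bounds for all sensors of a foot):

* 3D difference: mean norm of the per-sample vector difference,
  ``Δ3D = (1/N) Σ_k ‖x_i,k − x_j,k‖`` — always ≥ 0, blind to whether the
  disagreement is a constant offset or zero-mean oscillation;
* norm difference: mean difference of the per-sample vector norms,
  ``Δnorm = (1/N) Σ_k (‖x_i,k‖ − ‖x_j,k‖)`` — may be negative, and ≈ 0 for
  zero-mean disagreement, which separates offsets from oscillations.
  By the triangle inequality Δ3D ≥ |Δnorm| for every stride and pair.

Per-stride features on *v_min* strides characterize each position's
measurement chain:

* E_vmin — residual gyroscope energy (sum of squared norms, deg²/s²) in a
  40 ms window centered on the stride's starting t_vmin; any value above
  zero means the zero-velocity assumption is imperfect there;
* a_max — peak acceleration norm of the stride, a proxy for how strongly
  the heel-strike pressure wave reaches the sensor;
* PSD band powers — Welch estimate of the acceleration- and gyroscope-norm
  spectra (Hanning window of 64 samples, 50% overlap, segments zero-padded
  to 128 points); reported as mean power in the (0, 20] Hz band (the human
  movement itself) and the (80, 102.4) Hz band just below Nyquist (high
  frequency content linked to sampling-related integration errors).

The cross-sensor standard-deviation profile localizes *where* in the gait
cycle the six sensors disagree: per-sample, per-axis standard deviation
across positions, each stride resampled to 200 points and averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.signal.windows import hann

from .datatypes import ImuStream, SensorSet, StrideLabelList
from .events import VminStride

WELCH_NPERSEG = 64
WELCH_NFFT = 128
LOW_BAND = (0.0, 20.0)      # (exclusive, inclusive] — DC bin excluded
HIGH_BAND = (80.0, 102.4)   # (exclusive, exclusive)
EVMIN_WINDOW = 8            # samples, 40 ms at 204.8 Hz
PROFILE_SAMPLES = 200


def pairwise_diff_3d(
    stream_i: ImuStream, stream_j: ImuStream, start: int, end: int
) -> tuple[float, float]:
    """Mean per-sample vector-difference norm over one labeled stride."""
    if stream_i.n != stream_j.n:
        raise ValueError("streams differ in length")
    da = np.linalg.norm(stream_i.acc[start:end] - stream_j.acc[start:end], axis=1)
    dg = np.linalg.norm(stream_i.gyr[start:end] - stream_j.gyr[start:end], axis=1)
    return float(da.mean()), float(dg.mean())


def pairwise_diff_norm(
    stream_i: ImuStream, stream_j: ImuStream, start: int, end: int
) -> tuple[float, float]:
    """Mean per-sample difference of vector norms (signed) over a stride."""
    if stream_i.n != stream_j.n:
        raise ValueError("streams differ in length")
    da = np.linalg.norm(stream_i.acc[start:end], axis=1) - np.linalg.norm(
        stream_j.acc[start:end], axis=1
    )
    dg = np.linalg.norm(stream_i.gyr[start:end], axis=1) - np.linalg.norm(
        stream_j.gyr[start:end], axis=1
    )
    return float(da.mean()), float(dg.mean())


def residual_energy(
    gyr_dps: np.ndarray, tvmin: int, window: int = EVMIN_WINDOW
) -> tuple[float, bool]:
    """Summed squared gyroscope norm (deg²/s²) in the window around t_vmin.

    Returns the energy and a flag marking windows truncated by the signal
    edge (computed on the available samples).
    """
    a = tvmin - window // 2
    b = tvmin + window - window // 2
    truncated = a < 0 or b > len(gyr_dps)
    a, b = max(a, 0), min(b, len(gyr_dps))
    seg = gyr_dps[a:b]
    return float(np.einsum("ij,ij->", seg, seg)), truncated


def peak_acceleration(acc: np.ndarray, start: int, end: int) -> float:
    """Maximum acceleration norm within the stride, m/s²."""
    return float(np.linalg.norm(acc[start:end], axis=1).max())


def psd_band_power(
    signal_norm: np.ndarray,
    fs: float,
    *,
    detrend: bool | str = False,
) -> tuple[float, float] | None:
    """Mean Welch PSD in the low and high bands, or None for short strides.

    Uses a 64-sample Hanning window with 50% overlap, each segment
    zero-padded to 128 points. Band membership is decided by the bin
    center frequency: (0, 20] Hz excludes DC, (80, 102.4) Hz is open.
    """
    if len(signal_norm) < WELCH_NPERSEG:
        return None
    freqs, pxx = welch(
        signal_norm,
        fs=fs,
        window=hann(WELCH_NPERSEG),
        noverlap=WELCH_NPERSEG // 2,
        nfft=WELCH_NFFT,
        detrend=detrend,
    )
    low = (freqs > LOW_BAND[0]) & (freqs <= LOW_BAND[1])
    high = (freqs > HIGH_BAND[0]) & (freqs < HIGH_BAND[1])
    return float(pxx[low].mean()), float(pxx[high].mean())


def feature_row(
    stream: ImuStream,
    vmin: VminStride,
    *,
    detrend: bool | str = False,
) -> dict:
    """All per-stride features of one sensor over one v_min stride."""
    e_vmin, truncated = residual_energy(stream.gyr, vmin.start)
    a_norm = np.linalg.norm(stream.acc[vmin.start : vmin.end], axis=1)
    g_norm = np.linalg.norm(stream.gyr[vmin.start : vmin.end], axis=1)
    psd_acc = psd_band_power(a_norm, stream.fs, detrend=detrend)
    psd_gyr = psd_band_power(g_norm, stream.fs, detrend=detrend)
    return {
        "stride_id": vmin.stride_id,
        "position": vmin.position,
        "e_vmin": e_vmin,
        "e_vmin_truncated": truncated,
        "a_max": peak_acceleration(stream.acc, vmin.start, vmin.end),
        "psd_low_acc": psd_acc[0] if psd_acc else np.nan,
        "psd_high_acc": psd_acc[1] if psd_acc else np.nan,
        "psd_low_gyr": psd_gyr[0] if psd_gyr else np.nan,
        "psd_high_gyr": psd_gyr[1] if psd_gyr else np.nan,
    }


def feature_table(
    vmin_per_sensor: dict[str, list[VminStride]],
    sensor_set: SensorSet,
    **kw,
) -> pd.DataFrame:
    rows = [
        feature_row(sensor_set[pos], vm, **kw)
        for pos, vmins in vmin_per_sensor.items()
        for vm in vmins
    ]
    return pd.DataFrame(rows)


def pairwise_table(
    sensor_set: SensorSet, labels: StrideLabelList
) -> pd.DataFrame:
    """Δ3D and Δnorm for every sensor pair × labeled stride of one foot."""
    positions = list(sensor_set)
    rows = []
    for row in labels:
        s, e = int(row.start), int(row.end)
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                d3a, d3g = pairwise_diff_3d(sensor_set[i], sensor_set[j], s, e)
                dna, dng = pairwise_diff_norm(sensor_set[i], sensor_set[j], s, e)
                rows.append(
                    {
                        "stride_id": row.stride_id,
                        "sensor_i": i,
                        "sensor_j": j,
                        "d3d_acc": d3a,
                        "d3d_gyr": d3g,
                        "dnorm_acc": dna,
                        "dnorm_gyr": dng,
                    }
                )
    return pd.DataFrame(rows)


def cross_sensor_std_profile(
    sensor_set: SensorSet,
    labels: StrideLabelList,
    n_points: int = PROFILE_SAMPLES,
) -> pd.DataFrame:
    """Mean stride profile of the across-sensor standard deviation.

    For every sample of a labeled stride the standard deviation (sample
    denominator, n−1) across the six positions is taken per axis; each
    stride's profile is linearly resampled to ``n_points`` and averaged
    over strides. Columns: acc_x..z, gyr_x..z; rows: normalized gait-cycle
    position.
    """
    positions = list(sensor_set)
    acc = np.stack([sensor_set[p].acc for p in positions])  # (6, N, 3)
    gyr = np.stack([sensor_set[p].gyr for p in positions])
    grid = np.linspace(0.0, 1.0, n_points)
    profiles = []
    for row in labels:
        s, e = int(row.start), int(row.end)
        std6 = np.concatenate(
            [acc[:, s:e].std(axis=0, ddof=1), gyr[:, s:e].std(axis=0, ddof=1)], axis=1
        )  # (len, 6)
        x = np.linspace(0.0, 1.0, e - s)
        profiles.append(
            np.column_stack([np.interp(grid, x, std6[:, c]) for c in range(6)])
        )
    mean_profile = np.mean(profiles, axis=0)
    return pd.DataFrame(
        mean_profile,
        columns=["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"],
    )
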