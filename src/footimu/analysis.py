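"""Pipeline orchestration, error statistics and feature–error correlation.

``run_pipeline`` drives the full per-foot chain — per-test alignment,
border snapping, event detection, v_min strides, marker references, stride
selection, double integration, features — and returns tidy tables. The
error statistics follow the descriptive conventions of gait-validation
studies: signed error (IMU − heel reference; positive = overestimation by
the IMU), mean absolute error, interquartile range with linear-interpolation
quantiles, Tukey outliers (beyond Q1 − 1.5·IQR / Q3 + 1.5·IQR) and extreme
outliers (absolute error above 30 cm), grouped per sensor position and
walking-speed category.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import alignment as _alignment
from . import events as _events
from . import features as _features
from . import reference as _reference
from . import trajectory as _trajectory
from .datatypes import POSITIONS, SensorSet, Session, StrideLabelList

EXTREME_OUTLIER_M = 0.30

#: stride grouping categories and their membership rules
CATEGORIES = ("slow", "normal", "fast", "straight", "5min-walk", "all")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one place.

    Defaults reproduce the documented procedure; load overrides from a
    YAML/JSON mapping with :meth:`from_yaml`.
    """

    static_window_samples: int = _alignment.STATIC_WINDOW_SAMPLES
    static_var_threshold: float = _alignment.STATIC_VAR_THRESHOLD
    yaw_omega_threshold_dps: float = _alignment.YAW_OMEGA_THRESHOLD_DPS
    snap_window_ms: float = _events.SNAP_WINDOW_MS
    ic_search_fraction: float = _events.IC_SEARCH_FRACTION
    tvmin_window_samples: int = _events.TVMIN_WINDOW_SAMPLES
    sigmoid_steepness: float = _trajectory.SIGMOID_STEEPNESS
    gravity_mps2: float = 9.81
    init_window_samples: int = _trajectory.INIT_WINDOW_SAMPLES
    straightness_threshold_m: float = _reference.STRAIGHTNESS_THRESHOLD_M
    marker_max_gap_ms: float = _reference.MARKER_MAX_GAP_MS
    welch_detrend: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FootResult:
    """Intermediate products of one foot's pipeline run."""

    aligned: SensorSet
    labels: StrideLabelList
    events: pd.DataFrame
    vmin: dict[str, list]
    kept_ids: set
    exclusions: pd.DataFrame
    results: pd.DataFrame
    references: pd.DataFrame
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    std_profile: pd.DataFrame = field(default_factory=pd.DataFrame)


def align_session_foot(
    session: Session, foot: str, config: PipelineConfig
) -> SensorSet:
    """Align all sensors of one foot to the cavity sensor, per gait test.

    When the session metadata carries per-test sample ranges, each test is
    aligned independently (using its own standing phase) and the aligned
    slices are stitched back together; otherwise one global alignment is
    used.
    """
    sset = session.sensors[foot]
    tests = session.meta.get("tests", {}).get(foot)
    if not tests:
        aligned, _ = _alignment.align_sensor_set(
            sset,
            window=config.static_window_samples,
            var_threshold=config.static_var_threshold,
            omega_threshold=config.yaw_omega_threshold_dps,
        )
        return aligned
    acc = {p: np.empty_like(sset[p].acc) for p in POSITIONS}
    gyr = {p: np.empty_like(sset[p].gyr) for p in POSITIONS}
    for trow in tests:
        s, e = int(trow["start"]), int(trow["end"])
        sub = SensorSet(
            foot=foot, streams={p: sset[p].segment(s, e) for p in POSITIONS}
        )
        aligned_sub, _ = _alignment.align_sensor_set(
            sub,
            window=config.static_window_samples,
            var_threshold=config.static_var_threshold,
            omega_threshold=config.yaw_omega_threshold_dps,
        )
        for p in POSITIONS:
            acc[p][s:e] = aligned_sub[p].acc
            gyr[p][s:e] = aligned_sub[p].gyr
    streams = {}
    for p in POSITIONS:
        st = sset[p].copy()
        st.acc, st.gyr = acc[p], gyr[p]
        streams[p] = st
    return SensorSet(foot=foot, streams=streams)


def run_pipeline_foot(
    session: Session,
    foot: str,
    config: PipelineConfig | None = None,
    *,
    compute_features: bool = True,
) -> FootResult:
    config = config or PipelineConfig()
    aligned = align_session_foot(session, foot, config)
    fs = aligned.fs

    labels = _events.snap_stride_borders(
        aligned["instep"].gyr[:, _events.ML_AXIS],
        session.strides[foot],
        fs,
        config.snap_window_ms,
    )

    clock_offset = session.marker_clock_offset()
    cal = session.markers[foot]["CAL"]
    toe = session.markers[foot]["TOE"]

    event_tables = []
    vmin: dict[str, list] = {}
    refs: dict[str, list] = {}
    valid_ids: dict[str, set] = {}
    for pos in POSITIONS:
        evs = _events.detect_all_events(
            aligned[pos],
            labels,
            ic_search_fraction=config.ic_search_fraction,
            tvmin_window=config.tvmin_window_samples,
        )
        event_tables.append(_events.events_table(evs, pos))
        vmin[pos] = _events.build_vmin_strides(evs, labels, pos)
        valid_ids[pos] = {vm.stride_id for vm in vmin[pos]}
        refs[pos] = _reference.reference_lengths(
            vmin[pos], cal, toe, fs, clock_offset, config.marker_max_gap_ms
        )
    events_df = pd.concat(event_tables, ignore_index=True)

    kept, exclusions = _reference.select_strides(
        refs, valid_ids, config.straightness_threshold_m
    )

    rows = []
    for pos in POSITIONS:
        heel_by_id = {r.stride_id: r.heel for r in refs[pos]}
        toe_by_id = {r.stride_id: r.toe for r in refs[pos]}
        for vm in vmin[pos]:
            if vm.stride_id not in kept:
                continue
            length = _trajectory.stride_length(
                aligned[pos],
                vm,
                init_window=config.init_window_samples,
                steepness=config.sigmoid_steepness,
                gravity=config.gravity_mps2,
            )
            rows.append(
                {
                    "stride_id": vm.stride_id,
                    "foot": foot,
                    "position": pos,
                    "imu_length_m": length,
                    "heel_length_m": heel_by_id[vm.stride_id],
                    "toe_length_m": toe_by_id[vm.stride_id],
                }
            )
    results = pd.DataFrame(
        rows,
        columns=["stride_id", "foot", "position", "imu_length_m",
                 "heel_length_m", "toe_length_m"],
    )
    # a v_min stride carries the id of the stride its starting t_vmin belongs
    # to, but its interval contains the swing of the *adjacent* stride — so
    # per-stride ground truth (true length, straightness) maps from there
    meta = labels.df[
        [c for c in ("stride_id", "speed_category", "test_id") if c in labels.df.columns]
    ]
    if len(results):
        results = results.merge(meta, on="stride_id", how="left")
        truth_cols = [c for c in ("true_length_m", "straight") if c in labels.df.columns]
        if truth_cols:
            rows_by_idx = labels.df.reset_index(drop=True)
            shifted = {
                rows_by_idx.loc[k, "stride_id"]: rows_by_idx.loc[k1, truth_cols]
                for k, k1 in labels.adjacent_pairs()
            }
            for i, col in enumerate(truth_cols):
                results[col] = [
                    shifted[sid][col] if sid in shifted else np.nan
                    for sid in results["stride_id"]
                ]
        results["error_m"] = results["imu_length_m"] - results["heel_length_m"]
        results["abs_error_m"] = results["error_m"].abs()

    ref_rows = [
        {"stride_id": r.stride_id, "position": pos, "heel_m": r.heel, "toe_m": r.toe}
        for pos, rl in refs.items()
        for r in rl
    ]
    references = pd.DataFrame(ref_rows, columns=["stride_id", "position", "heel_m", "toe_m"])

    fr = FootResult(
        aligned=aligned, labels=labels, events=events_df, vmin=vmin,
        kept_ids=kept, exclusions=exclusions, results=results, references=references,
    )
    if compute_features:
        fr.features = _features.feature_table(vmin, aligned, detrend=config.welch_detrend)
        fr.pairwise = _features.pairwise_table(aligned, labels)
        fr.std_profile = _features.cross_sensor_std_profile(aligned, labels)
    return fr


def run_pipeline(
    session: Session,
    config: PipelineConfig | None = None,
    *,
    compute_features: bool = True,
) -> dict[str, FootResult]:
    return {
        foot: run_pipeline_foot(session, foot, config, compute_features=compute_features)
        for foot in session.feet
    }


def combined_results(per_foot: dict[str, FootResult]) -> pd.DataFrame:
    frames = [fr.results for fr in per_foot.values() if len(fr.results)]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# error statistics


def compute_stride_errors(
    imu_lengths: pd.DataFrame, reference_lengths: pd.DataFrame
) -> pd.DataFrame:
    """Join IMU and heel-reference lengths on stride_id × position.

    Signed error is IMU − reference (positive = overestimation by the
    IMU). Rows lacking either value are dropped.
    """
    keys = ["stride_id", "position"]
    for df, name in ((imu_lengths, "imu"), (reference_lengths, "reference")):
        if df.duplicated(keys).any():
            raise ValueError(f"duplicate stride_id × position keys in {name} table")
    merged = imu_lengths.merge(reference_lengths, on=keys, how="inner")
    merged = merged.dropna(subset=["imu_length_m", "heel_length_m"])
    merged["error_m"] = merged["imu_length_m"] - merged["heel_length_m"]
    merged["abs_error_m"] = merged["error_m"].abs()
    return merged


def assign_categories(results: pd.DataFrame) -> pd.DataFrame:
    """Expand stride results into the walking-speed grouping categories.

    ``slow/normal/fast`` contain the strides of the dedicated straight
    walk tests at that self-selected speed, ``straight`` their union,
    ``5min-walk`` the strides of the free continuous walk, ``all``
    everything. A stride belongs to several categories, so the output has
    one row per (stride × category).
    """
    frames = []
    is_5min = results["test_id"].astype(str).str.startswith("5min")
    for cat in CATEGORIES:
        if cat == "all":
            sub = results
        elif cat == "5min-walk":
            sub = results[is_5min]
        elif cat == "straight":
            sub = results[~is_5min]
        else:
            sub = results[~is_5min & (results["speed_category"] == cat)]
        sub = sub.copy()
        sub["category"] = cat
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def _tukey_outliers(errors: np.ndarray) -> tuple[float, int]:
    q1, q3 = np.quantile(errors, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    n_out = int(((errors < q1 - 1.5 * iqr) | (errors > q3 + 1.5 * iqr)).sum())
    return float(iqr), n_out


def summarize_errors(
    results: pd.DataFrame, groupby: tuple[str, ...] = ("position", "category")
) -> pd.DataFrame:
    """Descriptive error statistics per sensor × category.

    Expects a ``category`` column (see :func:`assign_categories`; plain
    grouping columns work too). Reports n, mean signed error, MAE, IQR of
    the signed error, Tukey outlier count and extreme outliers
    (|error| > 30 cm).
    """
    rows = []
    for key, grp in results.groupby(list(groupby), sort=True):
        err = grp["error_m"].to_numpy()
        if len(err) == 0:
            continue
        iqr, n_out = _tukey_outliers(err)
        rows.append(
            {
                **dict(zip(groupby, key if isinstance(key, tuple) else (key,))),
                "n": len(err),
                "mean_error_m": float(err.mean()),
                "mae_m": float(np.abs(err).mean()),
                "iqr_m": iqr,
                "outliers": n_out,
                "extreme_outliers": int((np.abs(err) > EXTREME_OUTLIER_M).sum()),
            }
        )
    return pd.DataFrame(rows)


def correlate_feature_error(
    joined: pd.DataFrame,
    feature: str,
    granularity: str = "stride",
) -> tuple[float | None, pd.DataFrame]:
    """Spearman rank correlation between a raw-data feature and |error|.

    ``joined`` must carry the feature column, ``abs_error_m`` and the keys
    ``position`` (and ``test_id`` for the test granularity). Granularities:
    ``stride`` (raw pairs), ``sensor-median`` (median per position),
    ``test-median`` (median per position × gait test). Returns the
    correlation (None when undefined: fewer than 3 pairs or a constant
    input) and the aggregated pair table used.
    """
    df = joined.dropna(subset=[feature, "abs_error_m"])
    if granularity == "stride":
        pairs = df[[feature, "abs_error_m"]].copy()
    elif granularity == "sensor-median":
        pairs = df.groupby("position")[[feature, "abs_error_m"]].median().reset_index()
    elif granularity == "test-median":
        pairs = (
            df.groupby(["position", "test_id"])[[feature, "abs_error_m"]]
            .median()
            .reset_index()
        )
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    x = pairs[feature].to_numpy(dtype=float)
    y = pairs["abs_error_m"].to_numpy(dtype=float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, pairs
    rho = spearmanr(x, y).statistic
    return float(rho), pairs
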