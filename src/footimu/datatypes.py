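"""In-memory data model shared by all pipeline stages.

A *session* is one synchronized recording of a subject walking: six IMU
streams per foot (one per mounting position on the shoe), heel (CAL) and
toe (TOE) optical-marker trajectories, and a table of labeled stride
borders. All stages of the pipeline consume and produce these containers.

Units are normalized on ingestion: acceleration in m/s² (specific force,
i.e. gravity included while the sensor rests), angular velocity in deg/s,
positions in meters. Stride intervals are 0-based, half-open ``[start, end)``
in samples of the IMU clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: canonical sensor mounting positions on the shoe
POSITIONS = ("insole", "cavity", "instep", "heel", "lateral", "medial")

#: optical marker labels used by the reference computation
MARKERS = ("CAL", "TOE")

FEET = ("left", "right")

IMU_RATE = 204.8  # Hz
MARKER_RATE = 100.0  # Hz
GRAVITY = 9.81  # m/s², world frame z-up


class SessionFormatError(ValueError):
    """A session (on disk or in memory) violates the documented schema."""


@dataclass
class ImuStream:
    """One sensor's synchronized 3-axis accelerometer + gyroscope stream.

    Parameters
    ----------
    position
        Mounting position label, one of :data:`POSITIONS`.
    foot
        ``"left"`` or ``"right"``.
    fs
        Sampling rate in Hz.
    acc
        ``(N, 3)`` specific force in m/s².
    gyr
        ``(N, 3)`` angular velocity in deg/s.
    """

    position: str
    foot: str
    fs: float
    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise SessionFormatError(f"acc must be (N, 3), got {self.acc.shape}")
        if self.gyr.shape != self.acc.shape:
            raise SessionFormatError(
                f"acc/gyr length mismatch for {self.position}: "
                f"{self.acc.shape} vs {self.gyr.shape}"
            )
        if self.fs <= 0:
            raise SessionFormatError("sampling rate must be > 0")
        if not (np.all(np.isfinite(self.acc)) and np.all(np.isfinite(self.gyr))):
            raise SessionFormatError(f"non-finite samples in stream {self.position}")

    @property
    def n(self) -> int:
        return self.acc.shape[0]

    def segment(self, start: int, end: int) -> "ImuStream":
        """Return the half-open slice ``[start, end)`` as a new stream."""
        return replace(self, acc=self.acc[start:end], gyr=self.gyr[start:end])

    def copy(self) -> "ImuStream":
        return replace(self, acc=self.acc.copy(), gyr=self.gyr.copy())


@dataclass
class SensorSet:
    """The six synchronized streams of one foot sharing a sample clock."""

    foot: str
    streams: Mapping[str, ImuStream]

    def __post_init__(self) -> None:
        missing = [p for p in POSITIONS if p not in self.streams]
        if missing:
            raise SessionFormatError(f"missing sensor position(s): {', '.join(missing)}")
        extra = [p for p in self.streams if p not in POSITIONS]
        if extra:
            raise SessionFormatError(f"unknown sensor position(s): {', '.join(extra)}")
        lengths = {s.n for s in self.streams.values()}
        if len(lengths) != 1:
            raise SessionFormatError(f"streams of foot {self.foot} differ in length: {lengths}")
        rates = {s.fs for s in self.streams.values()}
        if len(rates) != 1:
            raise SessionFormatError(f"streams of foot {self.foot} differ in rate: {rates}")

    def __getitem__(self, position: str) -> ImuStream:
        return self.streams[position]

    def __iter__(self) -> Iterator[str]:
        return iter(POSITIONS)

    @property
    def n(self) -> int:
        return next(iter(self.streams.values())).n

    @property
    def fs(self) -> float:
        return next(iter(self.streams.values())).fs


@dataclass
class MarkerStream:
    """Optical marker trajectory at the motion-capture rate.

    ``pos`` holds world coordinates in meters; frames flagged in ``gaps``
    were not tracked and carry NaN positions.
    """

    label: str
    fs: float
    pos: np.ndarray
    gaps: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.gaps = np.asarray(self.gaps, dtype=bool)
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise SessionFormatError(f"marker pos must be (N, 3), got {self.pos.shape}")
        if self.gaps.shape != (self.pos.shape[0],):
            raise SessionFormatError("gap mask length mismatch")
        if not np.all(np.isfinite(self.pos[~self.gaps])):
            raise SessionFormatError(f"non-finite positions outside gaps in marker {self.label}")

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def copy(self) -> "MarkerStream":
        return replace(self, pos=self.pos.copy(), gaps=self.gaps.copy())


#: columns every stride table carries; extra ground-truth columns are preserved
STRIDE_COLUMNS = ("stride_id", "start", "end")


class StrideLabelList:
    """Labeled stride borders of one foot.

    Wraps a DataFrame with at least ``stride_id, start, end`` (samples on
    the IMU clock, half-open). Strides are sorted and non-overlapping;
    adjacent strides share ``end == start`` and form *gait sequences* —
    maximal runs of adjacent strides with no break in between.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        for col in STRIDE_COLUMNS:
            if col not in df.columns:
                raise SessionFormatError(f"stride table missing column {col!r}")
        if len(df):
            if not (df["start"] < df["end"]).all():
                raise SessionFormatError("stride with start >= end")
            if not df["start"].is_monotonic_increasing:
                raise SessionFormatError("strides not sorted by start")
            if (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]).any():
                raise SessionFormatError("overlapping strides")
            if df["stride_id"].duplicated().any():
                raise SessionFormatError("duplicate stride_id")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def sequences(self) -> list[pd.DataFrame]:
        """Split into maximal runs of adjacent strides (shared borders)."""
        if not len(self.df):
            return []
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        breaks = np.flatnonzero(starts[1:] != ends[:-1]) + 1
        bounds = [0, *breaks, len(self.df)]
        return [self.df.iloc[a:b] for a, b in zip(bounds[:-1], bounds[1:])]

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (k, k+1) of strides sharing a border."""
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        return [(k, k + 1) for k in range(len(self.df) - 1) if ends[k] == starts[k + 1]]


@dataclass
class Session:
    """A full recording: per-foot sensor sets, markers and stride labels.

    ``meta`` carries the machine-readable provenance needed downstream:
    sampling rates, the IMU↔mocap clock offset, the simulation seed and
    the mounting table for synthetic sessions, and per-gait-test sample
    ranges (``tests``) used for grouping and per-test alignment.
    """

    sensors: dict[str, SensorSet]
    markers: dict[str, dict[str, MarkerStream]]
    strides: dict[str, StrideLabelList]
    meta: dict = field(default_factory=dict)

    @property
    def feet(self) -> tuple[str, ...]:
        return tuple(self.sensors)

    def marker_clock_offset(self) -> float:
        """World time of mocap frame 0 relative to IMU sample 0, seconds."""
        return float(self.meta.get("marker_clock_offset_s", 0.0))
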