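"""Read and write sessions as a directory of plain-text files.

Layout of a session directory::

    meta.json                     rates, clock offset, seed, mounts, tests
    imu_<foot>_<position>.csv     sample, acc_x..z [m/s²], gyr_x..z [deg/s]
    marker_<foot>_<label>.csv     frame, x, y, z [m], gap (0/1)
    strides_<foot>.csv            stride_id, start, end + ground-truth extras

CSV dialect: comma separated, ``.`` decimal, header row, UTF-8. Numeric
text round-trips to better than 1e−9 relative error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    POSITIONS,
    ImuStream,
    MarkerStream,
    SensorSet,
    Session,
    SessionFormatError,
    StrideLabelList,
)

_FLOAT_FMT = "%.12g"


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to ``path`` (created if missing)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "meta.json", "w", encoding="utf-8") as fh:
        json.dump({**session.meta, "feet": list(session.feet)}, fh, indent=2)
    for foot, sset in session.sensors.items():
        for position, stream in sset.streams.items():
            df = pd.DataFrame(
                {
                    "sample": np.arange(stream.n),
                    "acc_x": stream.acc[:, 0],
                    "acc_y": stream.acc[:, 1],
                    "acc_z": stream.acc[:, 2],
                    "gyr_x": stream.gyr[:, 0],
                    "gyr_y": stream.gyr[:, 1],
                    "gyr_z": stream.gyr[:, 2],
                }
            )
            df.to_csv(path / f"imu_{foot}_{position}.csv", index=False,
                      float_format=_FLOAT_FMT)
    for foot, mdict in session.markers.items():
        for label, marker in mdict.items():
            df = pd.DataFrame(
                {
                    "frame": np.arange(marker.n),
                    "x": marker.pos[:, 0],
                    "y": marker.pos[:, 1],
                    "z": marker.pos[:, 2],
                    "gap": marker.gaps.astype(int),
                }
            )
            df.to_csv(path / f"marker_{foot}_{label}.csv", index=False,
                      float_format=_FLOAT_FMT)
    for foot, strides in session.strides.items():
        strides.df.to_csv(path / f"strides_{foot}.csv", index=False,
                          float_format=_FLOAT_FMT)
    return path


def read_session(path: str | Path) -> Session:
    """Load a session directory back into the in-memory model.

    Raises :class:`SessionFormatError` naming the missing piece when a
    sensor position, marker file or stride table is absent, and validates
    all container invariants on the way in.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SessionFormatError(f"no meta.json in {path}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    feet = meta.pop("feet", None) or ["left", "right"]

    sensors: dict[str, SensorSet] = {}
    markers: dict[str, dict[str, MarkerStream]] = {}
    strides: dict[str, StrideLabelList] = {}
    fs = float(meta.get("imu_fs", 204.8))
    marker_fs = float(meta.get("marker_fs", 100.0))
    for foot in feet:
        streams = {}
        for position in POSITIONS:
            f = path / f"imu_{foot}_{position}.csv"
            if not f.exists():
                raise SessionFormatError(
                    f"missing sensor position '{position}' for foot {foot} ({f.name})"
                )
            df = pd.read_csv(f)
            streams[position] = ImuStream(
                position=position,
                foot=foot,
                fs=fs,
                acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
                gyr=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(),
            )
        sensors[foot] = SensorSet(foot=foot, streams=streams)

        markers[foot] = {}
        for label in ("CAL", "TOE"):
            f = path / f"marker_{foot}_{label}.csv"
            if not f.exists():
                raise SessionFormatError(f"missing marker '{label}' for foot {foot}")
            df = pd.read_csv(f)
            markers[foot][label] = MarkerStream(
                label=label,
                fs=marker_fs,
                pos=df[["x", "y", "z"]].to_numpy(),
                gaps=df["gap"].to_numpy().astype(bool),
            )

        f = path / f"strides_{foot}.csv"
        if not f.exists():
            raise SessionFormatError(f"missing stride table for foot {foot}")
        sdf = pd.read_csv(f)
        if "straight" in sdf.columns:
            sdf["straight"] = sdf["straight"].astype(bool)
        strides[foot] = StrideLabelList(sdf)

    return Session(sensors=sensors, markers=markers, strides=strides, meta=meta)
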