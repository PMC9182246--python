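"""Border snapping, gait-event detection and v_min stride construction."""

import numpy as np
import pandas as pd
import pytest

import footimu as fi
from footimu.datatypes import ImuStream, StrideLabelList
from footimu.events import (
    StrideEvents,
    build_vmin_strides,
    detect_all_events,
    detect_events,
    snap_stride_borders,
    validate_events,
)

FS = 204.8


def _labels(rows):
    return StrideLabelList(pd.DataFrame(rows, columns=["stride_id", "start", "end"]))


class TestSnapStrideBorders:
    def test_label_already_at_minimum_unchanged(self):
        g = np.ones(400)
        g[100] = -5.0
        g[250] = -7.0
        labels = _labels([(0, 100, 250)])
        out = snap_stride_borders(g, labels, FS)
        assert out.df.loc[0, "start"] == 100
        assert out.df.loc[0, "end"] == 250

    def test_offset_label_moves_to_windowed_minimum(self, rng):
        g = rng.normal(0, 0.1, 600)
        g[203] = -9.0
        g[405] = -8.0
        labels = _labels([(0, 199, 401)])  # 4 samples off both minima
        out = snap_stride_borders(g, labels, FS)
        half = round(25e-3 * FS)
        # brute-force argmin inside the window confirms the target
        assert out.df.loc[0, "start"] == 199 - half + np.argmin(g[199 - half:199 + half + 1])
        assert out.df.loc[0, "start"] == 203
        assert out.df.loc[0, "end"] == 405

    def test_shared_borders_stay_shared(self, rng):
        g = rng.normal(0, 1.0, 900)
        labels = _labels([(0, 100, 300), (1, 300, 500), (2, 500, 700)])
        out = snap_stride_borders(g, labels, FS)
        assert out.df.loc[0, "end"] == out.df.loc[1, "start"]
        assert out.df.loc[1, "end"] == out.df.loc[2, "start"]


def _synthetic_stride_stream():
    """One stride shaped like the detector expects: border dip, positive
    swing lobe, negative landing peak, then stillness."""
    n = 220
    gyr = np.zeros((n, 3))
    t = np.arange(n)
    gyr[:20, 1] = -40 * np.hanning(40)[20:]          # tail of the border dip
    gyr[25:95, 1] = 180 * np.hanning(70)             # swing
    gyr[105:135, 1] = -220 * np.hanning(30)          # landing / IC
    acc = np.zeros((n, 3))
    acc[:, 2] = 9.81
    acc[100:140, 2] += 30 * np.sin(np.linspace(0, np.pi, 40))
    acc[120, 2] = -15.0  # deceleration trough right at landing
    return ImuStream(position="cavity", foot="left", fs=FS, acc=acc, gyr=gyr)


class TestDetectEvents:
    def test_events_in_expected_order(self):
        st = _synthetic_stride_stream()
        ev = detect_events(st, 0, 220)
        assert ev.valid
        assert ev.tc < ev.ic < ev.tvmin
        assert 15 <= ev.tc <= 30
        assert 110 <= ev.ic <= 130

    def test_tvmin_inside_true_foot_flat(self, default_session, default_results):
        labels = default_results.labels.df.set_index("stride_id")
        truth = default_session.strides["left"].df.set_index("stride_id")
        ev_df = default_results.events
        checked = 0
        for row in ev_df[ev_df.valid].itertuples():
            lo = truth.loc[row.stride_id, "flat_start"]
            hi = truth.loc[row.stride_id, "flat_end"]
            assert lo - 2 <= row.tvmin <= hi + 2, row
            checked += 1
        assert checked > 30

    def test_monotone_signal_without_crossing_invalid(self):
        n = 200
        gyr = np.zeros((n, 3))
        gyr[:, 1] = np.linspace(-100, -10, n)  # never crosses zero
        acc = np.zeros((n, 3)); acc[:, 2] = 9.81
        st = ImuStream(position="cavity", foot="left", fs=FS, acc=acc, gyr=gyr)
        ev = detect_events(st, 0, n)
        assert not ev.valid
        assert ev.reason == "order"

    def test_tvmin_matches_exhaustive_window_scan(self, rng):
        st = _synthetic_stride_stream()
        st.gyr += rng.normal(0, 0.5, st.gyr.shape)
        ev = detect_events(st, 0, 220)
        energy = np.sum(st.gyr[ev.ic:220] ** 2, axis=1)
        best = min(
            range(len(energy) - 7),
            key=lambda s: energy[s:s + 8].sum(),
        )
        assert ev.tvmin == ev.ic + best + 4


class TestValidateEvents:
    def _ev(self, tc, ic, tvmin, start=0, end=100):
        return StrideEvents(stride_id=0, start=start, end=end, tc=tc, ic=ic,
                            tvmin=tvmin, valid=False, reason="none")

    def test_well_ordered_events_valid(self):
        ev = validate_events(self._ev(10, 50, 80))
        assert ev.valid and ev.reason == "none"

    def test_late_ic_rejected(self):
        ev = validate_events(self._ev(10, 65, 80))
        assert not ev.valid and ev.reason == "no_ic_60"

    def test_out_of_order_rejected(self):
        ev = validate_events(self._ev(10, 50, 40))
        assert not ev.valid and ev.reason == "order"


class TestBuildVminStrides:
    def _events(self, ids, tvmins, valid=None):
        valid = valid or [True] * len(ids)
        return [
            StrideEvents(stride_id=i, start=0, end=0, tc=1, ic=2, tvmin=tv,
                         valid=v, reason="none" if v else "order")
            for i, tv, v in zip(ids, tvmins, valid)
        ]

    def test_one_sequence_loses_one_stride(self):
        labels = _labels([(k, 100 * k, 100 * (k + 1)) for k in range(5)])
        evs = self._events(range(5), [60 + 100 * k for k in range(5)])
        out = build_vmin_strides(evs, labels, "cavity")
        assert len(out) == 4
        assert [vm.stride_id for vm in out] == [0, 1, 2, 3]

    def test_two_sequences_counting(self):
        rows = [(k, 100 * k, 100 * (k + 1)) for k in range(3)]
        rows += [(k + 3, 1000 + 100 * k, 1000 + 100 * (k + 1)) for k in range(4)]
        labels = _labels(rows)
        tv = [60 + r[1] for r in rows]
        out = build_vmin_strides(self._events([r[0] for r in rows], tv), labels, "cavity")
        assert len(out) == (3 - 1) + (4 - 1)

    def test_isolated_stride_yields_nothing(self):
        labels = _labels([(0, 0, 100)])
        out = build_vmin_strides(self._events([0], [60]), labels, "cavity")
        assert out == []

    def test_invalid_stride_breaks_the_chain(self):
        labels = _labels([(k, 100 * k, 100 * (k + 1)) for k in range(5)])
        evs = self._events(range(5), [60 + 100 * k for k in range(5)],
                           valid=[True, True, False, True, True])
        out = build_vmin_strides(evs, labels, "cavity")
        assert [vm.stride_id for vm in out] == [0, 3]

    def test_per_sensor_bounds_inside_union_of_strides(self, default_results):
        labels = default_results.labels.df.set_index("stride_id")
        for pos, vmins in default_results.vmin.items():
            for vm in vmins:
                row = labels.loc[vm.stride_id]
                nxt = labels[labels.start == row.end]
                assert row.start <= vm.start
                if len(nxt):
                    assert vm.end <= int(nxt.iloc[0].end)
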