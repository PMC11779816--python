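"""I/O round trips, grid gap-filling, and schedule validation."""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cagerhythm as cr
from cagerhythm.ingest import ValidationError, write_metrics_table

from conftest import make_trace


class TestActivityCsv:
    def test_grid_gap_becomes_missing(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "timestamp,animal_id,ali\n"
            "2024-01-01T00:00:00,m1,5\n"
            "2024-01-01T00:01:00,m1,0\n"
            "2024-01-01T00:03:00,m1,8\n"
        )
        (trace,) = cr.read_activity_csv(p)
        assert trace.n_bins == 4
        np.testing.assert_array_equal(trace.values[[0, 1, 3]], [5, 0, 8])
        assert np.isnan(trace.values[2])

    def test_ali_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,animal_id,ali\n2024-01-01T00:00:00,m1,120\n")
        with pytest.raises(ValidationError, match="outside"):
            cr.read_activity_csv(p)

    def test_duplicate_timestamp_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "timestamp,animal_id,ali\n"
            "2024-01-01T00:00:00,m1,5\n2024-01-01T00:00:00,m1,6\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            cr.read_activity_csv(p)

    def test_malformed_timestamp_names_row(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,animal_id,ali\nnot-a-time,m1,5\n")
        with pytest.raises(ValidationError, match="row 1"):
            cr.read_activity_csv(p)

    def test_round_trip_lossless(self, tmp_path):
        values = np.array([0.0, 12.5, np.nan, 99.99, 3.141592653589793])
        trace = make_trace(values, sex="F", genotype="CRY_dKO", animal_id="m7")
        cr.write_activity_csv([trace], tmp_path / "rt.csv")
        (back,) = cr.read_activity_csv(tmp_path / "rt.csv")
        np.testing.assert_array_equal(back.missing_mask, trace.missing_mask)
        np.testing.assert_allclose(back.values[~back.missing_mask],
                                   values[~np.isnan(values)], rtol=0, atol=0)
        assert (back.animal_id, back.sex, back.genotype) == ("m7", "F", "CRY_dKO")
        assert back.start_time == trace.start_time

    def test_wide_dialect(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "timestamp,m1,m2\n"
            "2024-01-01T00:00:00,1,2\n2024-01-01T00:01:00,3,4\n"
        )
        traces = cr.read_activity_csv(p)
        assert [t.animal_id for t in traces] == ["m1", "m2"]
        np.testing.assert_array_equal(traces[1].values, [2, 4])


class TestSchedule:
    def test_cycle_expansion(self):
        sched = cr.LightingSchedule.from_cycle("2024-01-01", n_days=2, lights_on_h=7)
        assert len(sched.episodes) == 4
        states = [e.state for e in sched.episodes]
        assert states == ["LIGHT", "DARK", "LIGHT", "DARK"]
        assert sum(e.duration_hours for e in sched.episodes) == 48.0
        assert sched.episodes[0].start.hour == 7

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(light_h=st.integers(1, 23), n_days=st.integers(1, 10))
    def test_cycle_expansion_property(self, light_h, n_days):
        """An H:D cycle over D days gives 2D episodes summing to 24D hours."""
        sched = cr.LightingSchedule.from_cycle(
            "2024-01-01", n_days=n_days, light_hours=light_h, dark_hours=24 - light_h)
        assert len(sched.episodes) == 2 * n_days
        assert sum(e.duration_hours for e in sched.episodes) == pytest.approx(24.0 * n_days)

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "start,end,state\n"
            "2024-01-01T00:00,2024-01-01T12:00,LIGHT\n"
            "2024-01-01T10:00,2024-01-01T22:00,DARK\n"
        )
        with pytest.raises(ValidationError, match="overlap"):
            cr.read_schedule(p)

    def test_unknown_state_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("start,end,state\n2024-01-01T00:00,2024-01-01T12:00,DIM\n")
        with pytest.raises(ValidationError, match="unknown"):
            cr.read_schedule(p)

    def test_dd_is_single_dark_episode(self):
        sched = cr.LightingSchedule.constant("2024-01-01", "2024-01-11", "DARK")
        assert len(sched.episodes) == 1
        assert sched.episodes[0].state == "DARK"
        assert sched.episodes[0].duration_hours == 240.0

    def test_json_round_trip(self, tmp_path):
        sched = cr.LightingSchedule.from_cycle("2024-01-01", n_days=1)
        p = tmp_path / "s.json"
        p.write_text(json.dumps([
            {"start": str(e.start), "end": str(e.end), "state": e.state, "lux": e.lux}
            for e in sched.episodes
        ]))
        back = cr.read_schedule(p)
        assert back.to_frame().equals(sched.to_frame())


class TestMetricsTable:
    def test_row_count_and_order(self, tmp_path):
        rows = [
            {"animal_id": a, "phase": ph, "is_value": 0.5}
            for a in ("m1", "m2") for ph in ("LD", "DD", "LL")
        ]
        write_metrics_table(rows, tmp_path / "m.csv")
        back = pd.read_csv(tmp_path / "m.csv")
        assert len(back) == 6
        assert list(back.columns[:2]) == ["animal_id", "phase"]

    def test_empty_gives_header_only(self, tmp_path):
        write_metrics_table([], tmp_path / "m.csv")
        text = (tmp_path / "m.csv").read_text().strip().splitlines()
        assert len(text) == 1

    def test_values_round_trip_full_precision(self, tmp_path):
        rows = [{"animal_id": "m1", "phase": "LD", "iv_value": 4 / 3, "ra_value": None}]
        write_metrics_table(rows, tmp_path / "m.csv")
        back = pd.read_csv(tmp_path / "m.csv")
        assert back["iv_value"].iloc[0] == 4 / 3
        assert np.isnan(back["ra_value"].iloc[0])  # undefined -> empty field


def test_phase_label_validation():
    with pytest.raises(ValidationError):
        cr.ProtocolPhase("WARMUP", 0, 7)
    with pytest.raises(ValidationError):
        cr.ProtocolPhase("DD", 5, 5)
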