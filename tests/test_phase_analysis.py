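"""Onset detection, phase shifts, re-entrainment and actogram matrices."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cagerhythm as cr
from cagerhythm.ingest import ValidationError
from cagerhythm.phase_analysis import circular_diff_h

from conftest import make_trace, square_day


def onset_series(onsets_by_day):
    days = sorted(onsets_by_day)
    return cr.OnsetSeries(
        day_index=np.array(days),
        onset_h=np.array([onsets_by_day[d] for d in days]),
        contrast=np.ones(len(days)),
    )


class TestDetectOnsets:
    def test_square_wave_onset_at_dark_onset(self):
        # activity starts 18:00; trace starts at midnight
        vals = np.tile(square_day(18.0, amp=20.0), 4)
        ons = cr.detect_onsets(make_trace(vals, start="2024-01-01 00:00"))
        np.testing.assert_allclose(ons.onset_h, 18.0, atol=1 / 60)
        np.testing.assert_allclose(ons.contrast, 20.0, atol=1e-9)

    def test_translation_equivariance(self):
        vals = np.tile(square_day(18.0 + 1.3, amp=20.0), 4)
        ons = cr.detect_onsets(make_trace(vals, start="2024-01-01 00:00"))
        np.testing.assert_allclose(ons.onset_h, 19.3, atol=1 / 60)

    def test_constant_trace_flagged_unreliable(self):
        ons = cr.detect_onsets(make_trace(np.full(2880, 5.0), start="2024-01-01 00:00"))
        np.testing.assert_allclose(ons.contrast, 0.0, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.5, 23.0), st.floats(0.5, 4.0), st.floats(0.0, 5.0))
    def test_affine_invariance_of_onset(self, start_h, gain, offset):
        """Scaling/offsetting activity must not move the detected onset."""
        vals = np.tile(square_day(start_h, amp=10.0, bin_minutes=6), 4)
        tr1 = make_trace(vals, bin_seconds=360, start="2024-01-01 00:00")
        tr2 = make_trace(gain * vals + offset, bin_seconds=360, start="2024-01-01 00:00")
        o1, o2 = cr.detect_onsets(tr1), cr.detect_onsets(tr2)
        np.testing.assert_allclose(o1.onset_h, o2.onset_h)

    def test_all_missing_day_skipped(self):
        vals = np.tile(square_day(18.0), 3)
        vals[1440:2880] = np.nan
        with pytest.warns(UserWarning, match="no data"):
            ons = cr.detect_onsets(make_trace(vals, start="2024-01-01 00:00"))
        assert list(ons.day_index) == [0, 2]


class TestPhaseShift:
    def test_delay(self):
        ps = cr.phase_shift(onset_series({-1: 20.0, 4: 21.3}))
        assert ps.shift_h == pytest.approx(1.3)

    def test_wraps_midnight(self):
        ps = cr.phase_shift(onset_series({-1: 23.5, 4: 0.5}))
        assert ps.shift_h == pytest.approx(1.0)

    def test_identical_onsets_zero(self):
        assert cr.phase_shift(onset_series({-1: 20.0, 4: 20.0})).shift_h == 0.0

    def test_drift_correction(self):
        # onsets advance 0.5 h/day (tau 23.5) plus a 1.3-h injected delay
        ons = onset_series({-1: 13.0, 4: 13.0 + 1.3 - 4 * 0.5})
        ps = cr.phase_shift(ons, free_run_period_h=23.5)
        assert ps.shift_h == pytest.approx(1.3)

    def test_missing_day_named(self):
        with pytest.raises(ValidationError, match="day 4"):
            cr.phase_shift(onset_series({-1: 20.0}))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0, 24, exclude_max=True), st.floats(0, 24, exclude_max=True))
    def test_antisymmetry(self, a, b):
        """Swapping the two days negates the shift (mod the (-12,12] mapping)."""
        fwd = cr.phase_shift(onset_series({-1: a, 4: b})).shift_h
        rev = cr.phase_shift(onset_series({-1: b, 4: a})).shift_h
        assert circular_diff_h(fwd + rev, 0.0) == pytest.approx(0.0, abs=1e-9)


class TestDaysToReentrain:
    def test_one_hour_per_day_advance(self):
        """Deviations 5,4,3,2,1,0,0 after a 6-h advance: re-entrained on day 6."""
        devs = {0 + d: (13.0 + max(6 - d, 0)) % 24 for d in range(1, 10)}
        res = cr.days_to_reentrain(onset_series(devs), target_onset_h=13.0, shift_day=0)
        assert res.days_to_reentrain == 6

    def test_no_shift_gives_one(self):
        ons = onset_series({d: 13.0 for d in range(0, 6)})
        assert cr.days_to_reentrain(ons, 13.0, shift_day=0).days_to_reentrain == 1

    def test_stuck_deviation_not_reached(self):
        ons = onset_series({d: 16.0 for d in range(0, 8)})
        res = cr.days_to_reentrain(ons, 13.0, shift_day=0)
        assert res.days_to_reentrain is None

    def test_transient_crossing_needs_stable_days(self):
        ons = onset_series({0: 18.0, 1: 13.1, 2: 17.0, 3: 13.0, 4: 13.0})
        res = cr.days_to_reentrain(ons, 13.0, shift_day=0, stable_days=2)
        assert res.days_to_reentrain == 3


class TestActogram:
    def test_double_plot_shape_and_padding(self):
        tr = make_trace(np.arange(3 * 1440, dtype=float) % 97, start="2024-01-01 00:00")
        m = cr.build_actogram(tr, bins_per_row=288, double=True)
        assert m.day_rows.shape == (3, 576)
        assert np.isnan(m.day_rows[2, 288:]).all()
        np.testing.assert_array_equal(m.day_rows[0, 288:], m.day_rows[1, :288])

    def test_single_plot_matches_split_days(self):
        vals = np.arange(2 * 1440, dtype=float) % 97
        tr = make_trace(vals, start="2024-01-01 00:00")
        m = cr.build_actogram(tr, bins_per_row=1440, double=False)
        segs = cr.split_days(tr)
        np.testing.assert_array_equal(m.day_rows[0], segs.segments[0])
        np.testing.assert_array_equal(m.day_rows[1], segs.segments[1])

    def test_activity_conserved(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 50, 2 * 1440)
        tr = make_trace(vals, start="2024-01-01 00:00")
        m = cr.build_actogram(tr, bins_per_row=288, double=True)
        left_sum = np.nansum(m.day_rows[:, :288]) * 5  # 5-min bins
        assert left_sum == pytest.approx(vals.sum(), rel=1e-9)

    def test_render_writes_file(self, tmp_path):
        tr = make_trace(np.tile(square_day(18.0), 3), start="2024-01-01 00:00")
        m = cr.build_actogram(tr)
        out = tmp_path / "act.png"
        cr.phase_analysis.render_actogram(m, out)
        assert out.stat().st_size > 0
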