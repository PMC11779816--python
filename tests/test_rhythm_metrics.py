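"""Closed forms and invariances of the rhythm metrics."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import cagerhythm as cr
from cagerhythm.ingest import ValidationError
from cagerhythm.rhythm_metrics import (
    activity_bouts,
    chi_square_periodogram,
    interdaily_stability,
    intradaily_variability,
    light_phase_activity,
    relative_amplitude,
    total_activity,
)

from conftest import make_trace, square_day


class TestPeriodogram:
    def test_noiseless_square_qp_equals_n_prime(self):
        """A clean 24-h square wave folds with zero residual: Qp = N'."""
        vals = np.tile(square_day(12.0, bin_minutes=6), 7)  # 1680 six-min bins
        pg = chi_square_periodogram(vals, 0.1)
        assert pg.peak_period_h == 24.0
        assert pg.max_qp == pytest.approx(1680.0)
        assert pg.n_points == 1680
        assert pg.significant

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            chi_square_periodogram(np.full(1000, 5.0), 0.1)

    def test_short_record_rejected(self):
        with pytest.raises(ValidationError, match="3 cycles"):
            chi_square_periodogram(np.random.default_rng(0).normal(size=200), 0.1)

    def test_missing_bins_do_not_shift_peak(self):
        vals = np.tile(square_day(12.0, bin_minutes=6), 7)
        vals[100:110] = np.nan
        pg = chi_square_periodogram(vals, 0.1)
        assert pg.peak_period_h == 24.0

    def test_peak_is_a_candidate_and_df_matches(self):
        vals = np.tile(square_day(12.0, bin_minutes=6), 7)
        pg = chi_square_periodogram(vals, 0.1)
        assert pg.peak_period_h in pg.candidate_periods
        i = np.flatnonzero(pg.candidate_periods == pg.peak_period_h)[0]
        assert pg.df[i] == int(round(pg.peak_period_h / 0.1)) - 1


class TestInterdailyStability:
    def test_identical_days_give_one(self):
        assert interdaily_stability([0, 1, 0, 1], bins_per_day=2) == pytest.approx(1.0)

    def test_antiphase_days_give_zero(self):
        assert interdaily_stability([0, 1, 1, 0], bins_per_day=2) == pytest.approx(0.0)

    def test_iid_noise_expectation_one_over_days(self):
        """For i.i.d. noise over D days, E[IS] ~ 1/D (day-averaging variance)."""
        rng = np.random.default_rng(7)
        d = 4
        vals = [interdaily_stability(rng.normal(size=24 * d), 24) for _ in range(300)]
        assert np.mean(vals) == pytest.approx(1 / d, abs=0.03)

    def test_constant_series_undefined(self):
        assert interdaily_stability(np.ones(48), 24) is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(float, st.integers(2, 6).map(lambda d: 24 * d),
                  elements=st.floats(0, 100, width=32)),
           st.floats(0.1, 5), st.floats(-10, 10))
    def test_bounded_and_affine_invariant(self, vals, a, b):
        is1 = interdaily_stability(vals, 24)
        if is1 is None:
            return
        assert -1e-9 <= is1 <= 1 + 1e-9
        is2 = interdaily_stability(a * vals + b, 24)
        assert is2 == pytest.approx(is1, rel=1e-6, abs=1e-9)


class TestIntradailyVariability:
    @pytest.mark.parametrize("vals,expected", [([0, 1, 0, 1], 4.0), ([0, 0, 1, 1], 4 / 3)])
    def test_hand_computed_examples(self, vals, expected):
        assert intradaily_variability(vals) == pytest.approx(expected)

    def test_white_noise_tends_to_two(self):
        rng = np.random.default_rng(11)
        assert intradaily_variability(rng.normal(size=10080)) == pytest.approx(2.0, abs=0.1)

    def test_gap_spanning_diffs_skipped(self):
        # the 0->1 jump is hidden behind a gap and must not count
        with_gap = intradaily_variability([0, 0, 0, np.nan, 1, 1, 1])
        assert with_gap == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(float, st.integers(4, 100), elements=st.floats(0, 100, width=32)),
           st.floats(0.1, 5), st.floats(-10, 10))
    def test_affine_invariant(self, vals, a, b):
        iv1 = intradaily_variability(vals)
        if iv1 is None:
            return
        assert intradaily_variability(a * vals + b) == pytest.approx(iv1, rel=1e-6, abs=1e-9)


class TestRelativeAmplitude:
    def test_nocturnal_square_gives_one(self):
        prof = np.r_[np.zeros(12), np.full(12, 8.0)]
        assert relative_amplitude(prof) == pytest.approx(1.0)

    def test_constant_profile_gives_zero(self):
        assert relative_amplitude(np.full(24, 5.0)) == pytest.approx(0.0)

    def test_plateau_profile(self):
        """12 h at 10, 12 h at 2: best windows sit inside each plateau."""
        prof = np.r_[np.full(12, 10.0), np.full(12, 2.0)]
        assert relative_amplitude(prof) == pytest.approx(8 / 12)

    def test_all_zero_profile_undefined(self):
        assert relative_amplitude(np.zeros(24)) is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(float, st.just(24), elements=st.floats(0, 100, width=32)),
           st.floats(0.1, 10))
    def test_scale_invariant_and_bounded(self, prof, a):
        ra = relative_amplitude(prof)
        if ra is None:
            return
        assert 0 <= ra <= 1 + 1e-9
        assert relative_amplitude(a * prof) == pytest.approx(ra, rel=1e-6, abs=1e-9)


class TestBouts:
    def test_two_runs(self):
        b = activity_bouts([0, 5, 7, 0, 0, 3, 0])
        assert b.class_counts[0] == 1  # the 1-min run
        assert b.class_counts[1] == 1  # the 2-min run
        assert b.n_bouts == 2

    def test_all_zero_gives_no_bouts(self):
        assert activity_bouts(np.zeros(100)).n_bouts == 0

    def test_gap_bridged(self):
        b = activity_bouts([5, 0, 5], max_gap_bins=1)
        assert b.n_bouts == 1
        assert b.class_counts[2] == 1  # bridged run of 3 min

    def test_missing_breaks_bouts(self):
        b = activity_bouts([5, np.nan, 5], max_gap_bins=1)
        assert b.n_bouts == 2

    def test_long_runs_pool_in_top_class(self):
        b = activity_bouts(np.r_[np.full(30, 4.0), np.zeros(3), np.full(9, 4.0)])
        assert b.class_counts[7] == 2
        assert b.n_bouts == 2


class TestLightPhaseAndTotals:
    def _ld(self):
        return cr.LightingSchedule.from_cycle("2024-01-01", 2, lights_on_h=0)

    def test_perfectly_nocturnal_is_zero(self):
        tr = make_trace(np.tile(square_day(12.0), 2), start="2024-01-01 00:00")
        assert light_phase_activity(tr, self._ld()) == pytest.approx(0.0)

    def test_constant_activity_is_half(self):
        tr = make_trace(np.full(2880, 4.0), start="2024-01-01 00:00")
        assert light_phase_activity(tr, self._ld()) == pytest.approx(0.5)

    def test_one_to_three_contrast(self):
        day = np.r_[np.full(720, 1.0), np.full(720, 3.0)]
        tr = make_trace(np.tile(day, 2), start="2024-01-01 00:00")
        assert light_phase_activity(tr, self._ld()) == pytest.approx(0.25)

    def test_dd_is_undefined(self):
        dd = cr.LightingSchedule.constant("2024-01-01", "2024-01-03", "DARK")
        tr = make_trace(np.full(2880, 4.0), start="2024-01-01 00:00")
        assert light_phase_activity(tr, dd) is None

    def test_total_constant_day(self):
        _, mean = total_activity(make_trace(np.full(1440, 2.0)))
        assert mean == pytest.approx(2880.0)

    def test_total_rescales_welfare_gap(self):
        vals = np.full(1440, 2.0)
        vals[600:605] = np.nan
        _, mean = total_activity(make_trace(vals))
        assert mean == pytest.approx(2880.0)

    def test_total_zero_trace(self):
        _, mean = total_activity(make_trace(np.zeros(1440)))
        assert mean == 0.0
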