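"""Unit and property tests for the nonparametric RAR indicators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import helpers
from actirhythm import (
    ConstantSeriesError,
    EpochSeries,
    HourlySeries,
    InsufficientDaysError,
    ValidationError,
    composite_rar,
    hourly_average,
    interdaily_stability,
    intradaily_variability,
    m10_l5_per_day,
    relative_amplitude,
)

MID = pd.Timestamp("2024-01-01 00:00")


def _epochs(counts):
    return EpochSeries(MID, np.asarray(counts, dtype=float))


class TestHourlyAverage:
    def test_constant_series(self):
        h = hourly_average(_epochs(np.full(2 * 1440, 3.5)))
        assert h.values.shape == (2, 24)
        assert np.all(h.values == 3.5)

    def test_single_spike_spreads_to_its_hour(self):
        counts = np.zeros(1440)
        counts[5 * 60 + 17] = 60.0
        h = hourly_average(_epochs(counts))
        expected = np.zeros(24)
        expected[5] = 1.0
        assert np.allclose(h.values[0], expected)

    def test_matches_per_hour_loop(self, rng):
        counts = rng.uniform(0, 100, 3 * 1440)
        h = hourly_average(_epochs(counts))
        for d in range(3):
            for hr in range(24):
                block = counts[d * 1440 + hr * 60 : d * 1440 + hr * 60 + 60]
                assert h.values[d, hr] == pytest.approx(float(np.mean(block)), rel=1e-12)

    def test_partial_hours_follow_validity_threshold(self, rng):
        counts = rng.uniform(1, 10, 1440)
        counts[:16] = np.nan  # hour 0: 44 valid minutes -> invalid
        counts[60:75] = np.nan  # hour 1: 45 valid minutes -> still valid
        h = hourly_average(_epochs(counts))
        assert np.isnan(h.values[0, 0])
        assert h.values[0, 1] == pytest.approx(float(np.nanmean(counts[60:120])))

    def test_non_midnight_start_rejected(self):
        with pytest.raises(ValidationError):
            hourly_average(EpochSeries(MID + pd.Timedelta(minutes=30), np.ones(1440)))

    def test_partial_day_rejected(self):
        with pytest.raises(ValidationError):
            hourly_average(_epochs(np.ones(1500)))


class TestStabilityAndFragmentation:
    def test_identical_days_give_is_one(self, rng):
        day = rng.uniform(0, 10, 24)
        h = HourlySeries(MID, np.tile(day, (7, 1)))
        assert interdaily_stability(h) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_undefined(self):
        h = HourlySeries(MID, np.full((7, 24), 2.0))
        with pytest.raises(ConstantSeriesError, match="constant"):
            interdaily_stability(h)
        with pytest.raises(ConstantSeriesError, match="constant"):
            intradaily_variability(h)

    def test_alternating_series_has_iv_four(self):
        vals = np.where(np.arange(7 * 24) % 2 == 0, 1.0, 5.0).reshape(7, 24)
        assert intradaily_variability(HourlySeries(MID, vals)) == pytest.approx(4.0, abs=1e-12)

    def test_sampled_sinusoid_iv_matches_lag_one_form(self):
        hours = np.arange(7 * 24)
        vals = (5 + np.cos(2 * np.pi * hours / 24)).reshape(7, 24)
        expected = 2 * (1 - np.cos(2 * np.pi / 24))
        assert intradaily_variability(HourlySeries(MID, vals)) == pytest.approx(expected, abs=0.005)

    def test_is_iv_match_bruteforce(self, rng):
        days = rng.uniform(0, 50, (3, 24))
        h = HourlySeries(MID, days)
        assert interdaily_stability(h) == pytest.approx(helpers.is_bruteforce(days), rel=1e-12)
        assert intradaily_variability(h) == pytest.approx(helpers.iv_bruteforce(days), rel=1e-12)

    def test_excluded_day_breaks_first_difference_chain(self, rng):
        days = rng.uniform(0, 50, (4, 24))
        h = HourlySeries(MID, days, day_numbers=np.array([0, 1, 3, 4]))  # day 2 excluded
        x = days.ravel()
        grand = x.mean()
        diffs = np.diff(x) ** 2
        keep = np.ones(len(diffs), dtype=bool)
        keep[2 * 24 - 1] = False  # pair spanning the excluded day
        expected = (x.size * diffs[keep].sum()) / (keep.sum() * ((x - grand) ** 2).sum())
        assert intradaily_variability(h) == pytest.approx(expected, rel=1e-12)


class TestWindows:
    def test_block_day(self):
        day = np.concatenate([np.full(600, 10.0), np.zeros(840)])
        per_day, excluded = m10_l5_per_day(_epochs(day))
        assert excluded == []
        (d,) = per_day
        assert d.m10 == pytest.approx(10.0)
        assert d.m10_onset_min == 0 and d.m10_onset_clock == "00:00"
        assert d.l5 == pytest.approx(0.0)

    def test_constant_day(self):
        (d,), _ = m10_l5_per_day(_epochs(np.full(1440, 4.2)))
        assert d.m10 == pytest.approx(4.2) and d.l5 == pytest.approx(4.2)
        # earliest-onset tie break
        assert d.m10_onset_min == 0 and d.l5_onset_min == 0

    def test_random_day_matches_exhaustive_scan(self, rng):
        day = rng.uniform(0, 80, 1440)
        (d,), _ = m10_l5_per_day(_epochs(day))
        m10, mi, l5, li = helpers.m10_l5_bruteforce(day)
        assert d.m10 == pytest.approx(m10, rel=1e-12) and d.m10_onset_min == mi
        assert d.l5 == pytest.approx(l5, rel=1e-12) and d.l5_onset_min == li

    def test_wrap_allows_night_spanning_l5(self):
        # activity only 22:00-02:00 is quiet; without wrap L5 must fit inside
        day = np.full(1440, 20.0)
        day[:120] = 0.0
        day[-120:] = 0.0
        (no_wrap,), _ = m10_l5_per_day(_epochs(day))
        (wrapped,), _ = m10_l5_per_day(_epochs(day), wrap=True)
        assert wrapped.l5 < no_wrap.l5
        assert wrapped.l5 == pytest.approx(60 * 20.0 / 300)  # 240 quiet + 60 active minutes

    def test_hourly_resolution_matches_hour_scan(self, rng):
        day = rng.uniform(0, 80, 1440)
        (d,), _ = m10_l5_per_day(_epochs(day), resolution="hour")
        hours = day.reshape(24, 60).mean(axis=1)
        m10s = [hours[i : i + 10].mean() for i in range(15)]
        l5s = [hours[i : i + 5].mean() for i in range(20)]
        assert d.m10 == pytest.approx(max(m10s), rel=1e-12)
        assert d.l5 == pytest.approx(min(l5s), rel=1e-12)
        assert d.m10_onset_min == int(np.argmax(m10s)) * 60


class TestRelativeAmplitude:
    def test_zero_l5_gives_maximal_amplitude(self):
        assert relative_amplitude(10.0, 0.0) == pytest.approx(1.0)

    def test_zero_activity_is_nan(self):
        assert np.isnan(relative_amplitude(0.0, 0.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            relative_amplitude(-1.0, 0.0)


class TestComposite:
    def test_insufficient_days_refused_unless_forced(self, rng):
        counts = rng.uniform(0, 10, 5 * 1440)
        with pytest.raises(InsufficientDaysError, match="insufficient days"):
            composite_rar(_epochs(counts))
        m = composite_rar(_epochs(counts), force=True)
        assert m.n_days_used == 5

    def test_invalid_day_excluded_everywhere(self, week_epochs):
        counts = week_epochs.counts.copy()
        counts[3 * 1440 + 300 : 3 * 1440 + 330] = np.nan  # kill one hour of day 3
        m = composite_rar(EpochSeries(week_epochs.start_time, counts), min_days=6)
        full = composite_rar(week_epochs)
        assert m.excluded_days == [3]
        assert m.n_days_used == 6
        assert [d.day for d in m.per_day] == [0, 1, 2, 4, 5, 6]
        # retained per-day windows agree with the complete-data run
        kept = [d for d in full.per_day if d.day != 3]
        assert np.allclose([d.m10 for d in m.per_day], [d.m10 for d in kept])

    def test_composite_is_mean_of_daily_windows(self, week_epochs):
        m = composite_rar(week_epochs)
        assert m.M10 == pytest.approx(np.mean([d.m10 for d in m.per_day]))
        assert m.L5 == pytest.approx(np.mean([d.l5 for d in m.per_day]))
        assert m.RA == pytest.approx((m.M10 - m.L5) / (m.M10 + m.L5))

    def test_scale_invariance_exact(self, week_epochs):
        k = 7.3
        base = composite_rar(week_epochs)
        scaled = composite_rar(EpochSeries(week_epochs.start_time, k * week_epochs.counts))
        assert scaled.IS == pytest.approx(base.IS, rel=1e-12)
        assert scaled.IV == pytest.approx(base.IV, rel=1e-12)
        assert scaled.RA == pytest.approx(base.RA, rel=1e-12)
        assert scaled.M10 == pytest.approx(k * base.M10, rel=1e-12)
        assert scaled.L5 == pytest.approx(k * base.L5, rel=1e-12)

    def test_time_shift_covariance(self, week_epochs):
        shift = 120  # whole hours keep the hourly binning aligned
        days = week_epochs.counts.reshape(7, 1440)
        shifted = EpochSeries(week_epochs.start_time, np.roll(days, shift, axis=1).ravel())
        base = composite_rar(week_epochs, wrap=True)
        moved = composite_rar(shifted, wrap=True)
        assert moved.IS == pytest.approx(base.IS, rel=1e-12)
        assert moved.M10 == pytest.approx(base.M10, rel=1e-12)
        assert moved.L5 == pytest.approx(base.L5, rel=1e-12)
        assert moved.RA == pytest.approx(base.RA, rel=1e-12)
        for b, s in zip(base.per_day, moved.per_day):
            assert (b.m10_onset_min + shift) % 1440 == s.m10_onset_min
            assert (b.l5_onset_min + shift) % 1440 == s.l5_onset_min
        # IV is only shift-invariant up to day-boundary edge effects
        assert moved.IV == pytest.approx(base.IV, rel=0.05)

    @given(
        counts=hnp.arrays(
            float,
            shape=2 * 1440,
            elements=st.floats(min_value=0, max_value=1000),
        ).filter(lambda c: np.ptp(c) > 0 and np.ptp(c.reshape(2, 24, 60).mean(axis=2)) > 0)
    )
    def test_range_invariants(self, counts):
        m = composite_rar(_epochs(counts), min_days=2)
        assert 0.0 <= m.IS <= 1.0 + 1e-9
        assert m.IV >= 0.0
        assert m.M10 >= m.L5 >= 0.0
        assert 0.0 <= m.RA <= 1.0
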