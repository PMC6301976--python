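"""ENSO classification, return periods, and stochastic schedule sampling."""

import io

import numpy as np
import pytest

import reefcast as rc
from reefcast.errors import (
    ConfigurationError,
    DataError,
    InsufficientEventsError,
    MalformedSeriesError,
)
from reefcast.events import EventCategory, SEASONS


def oni_from_anomalies(anoms, year0=1950):
    flat = np.arange(len(anoms))
    return rc.OniSeries(years=year0 + flat // 12, seasons=flat % 12, anomalies=np.asarray(anoms, float))


def brute_force_events(anoms):
    """Independent oracle: scan every index, collect maximal hot runs >= 5."""
    hot = [a >= 0.5 for a in anoms]
    runs, start = [], None
    for i, h in enumerate(hot + [False]):
        if h and start is None:
            start = i
        elif not h and start is not None:
            if i - start >= 5:
                runs.append((start, i - 1, max(anoms[start:i])))
            start = None
    return runs


class TestClassification:
    def test_all_zero_series_has_no_events(self):
        assert rc.classify_enso_events(oni_from_anomalies(np.zeros(120))) == []

    def test_six_season_run_peaking_at_1p6_is_one_strong_event(self):
        anoms = np.zeros(60)
        anoms[20:26] = [0.6, 1.0, 1.6, 1.2, 0.8, 0.5]
        events = rc.classify_enso_events(oni_from_anomalies(anoms))
        assert len(events) == 1
        ev = events[0]
        assert ev.category is EventCategory.strong
        assert ev.peak_anomaly == pytest.approx(1.6)
        assert ev.n_seasons == 6

    def test_four_season_run_is_too_short(self):
        anoms = np.zeros(60)
        anoms[20:24] = 0.8
        assert rc.classify_enso_events(oni_from_anomalies(anoms)) == []

    def test_threshold_is_inclusive(self):
        # "at or above" 0.5: a run of exact 0.5 values counts
        anoms = np.zeros(60)
        anoms[10:15] = 0.5
        events = rc.classify_enso_events(oni_from_anomalies(anoms))
        assert len(events) == 1
        assert events[0].category is EventCategory.weak

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        anoms = np.round(r.normal(0.3, 0.6, size=240), 2)
        anoms = np.clip(anoms, -4.9, 4.9)
        got = rc.classify_enso_events(oni_from_anomalies(anoms))
        want = brute_force_events(list(anoms))
        assert len(got) == len(want)
        for ev, (i, j, peak) in zip(got, want):
            assert ev.start_year * 12 + ev.start_season == 1950 * 12 + i
            assert ev.end_year * 12 + ev.end_season == 1950 * 12 + j
            assert ev.peak_anomaly == pytest.approx(peak)

    def test_invariant_to_subthreshold_padding(self):
        anoms = np.zeros(36)
        anoms[5:12] = [0.7, 1.1, 2.3, 1.9, 1.0, 0.6, 0.5]
        base = rc.classify_enso_events(oni_from_anomalies(anoms))
        padded = np.concatenate([np.full(12, 0.4), anoms, np.full(12, 0.49)])
        shifted = rc.classify_enso_events(oni_from_anomalies(padded))
        assert len(shifted) == len(base) == 1
        assert shifted[0].peak_anomaly == base[0].peak_anomaly
        assert shifted[0].category is base[0].category
        # start shifts by exactly the 12 prepended seasons
        flat = lambda e: e.start_year * 12 + e.start_season
        assert flat(shifted[0]) - flat(base[0]) == 12

    def test_gap_in_season_sequence_rejected(self):
        with pytest.raises(MalformedSeriesError, match="contiguous"):
            rc.OniSeries(
                years=np.array([1950, 1950, 1950]),
                seasons=np.array([0, 1, 3]),  # skips FMA
                anomalies=np.zeros(3),
            )

    @pytest.mark.parametrize(
        "peak,cat",
        [(0.5, "weak"), (0.9, "weak"), (1.0, "moderate"), (1.4, "moderate"),
         (1.5, "strong"), (1.9, "strong"), (2.0, "very_strong"), (2.6, "very_strong")],
    )
    def test_category_boundaries_closed_on_left(self, peak, cat):
        assert EventCategory.from_peak(peak).name == cat


class TestPeriodicity:
    @staticmethod
    def events_at_years(years, peak=1.6):
        out = []
        for y in years:
            anoms = np.zeros(72)
            anoms[6:12] = peak
            sub = rc.classify_enso_events(oni_from_anomalies(anoms, year0=y))
            out.extend(sub)
        return out

    def test_regular_five_year_spacing(self):
        events = self.events_at_years([1950, 1955, 1960])
        st = rc.periodicity_stats(events)
        assert (st.mean, st.median, st.sd) == (5.0, 5.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_gap_statistics(self, seed):
        r = np.random.default_rng(100 + seed)
        n = int(r.integers(2, 7))
        years = np.sort(r.choice(np.arange(1950, 2010, 7), size=n, replace=False))
        events = self.events_at_years(list(years))
        st = rc.periodicity_stats(events)
        gaps = np.diff(sorted(years))
        assert st.mean == pytest.approx(np.mean(gaps))
        assert st.median == pytest.approx(np.median(gaps))
        expect_sd = np.std(gaps, ddof=1) if len(gaps) > 1 else 0.0
        assert st.sd == pytest.approx(expect_sd)

    def test_category_filter(self):
        events = self.events_at_years([1950, 1960], peak=0.7) + self.events_at_years(
            [1955, 1971], peak=1.8
        )
        st = rc.periodicity_stats(events, min_category="strong")
        assert st.n_events == 2
        assert st.mean == 16.0

    def test_fewer_than_two_events_rejected(self):
        events = self.events_at_years([1950])
        with pytest.raises(InsufficientEventsError):
            rc.periodicity_stats(events)


class TestOniReader:
    def test_wide_noaa_layout(self, tmp_path):
        header = "YEAR," + ",".join(SEASONS)
        rows = ["1950," + ",".join("0.0" for _ in SEASONS), "1951," + ",".join("0.6" for _ in SEASONS)]
        path = tmp_path / "oni_wide.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        series = rc.read_oni(path)
        assert len(series) == 24
        assert series.anomalies[12] == 0.6

    def test_tidy_layout_with_labels(self, tmp_path):
        lines = ["year,season,anomaly"]
        for i, s in enumerate(SEASONS):
            lines.append(f"1950,{s},{0.1 * i:.1f}")
        path = tmp_path / "oni_tidy.csv"
        path.write_text("\n".join(lines) + "\n")
        series = rc.read_oni(path)
        assert len(series) == 12
        assert series.anomalies[3] == pytest.approx(0.3)

    def test_unrecognized_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("when,how_hot\n1950,0.1\n")
        with pytest.raises(DataError, match="layout"):
            rc.read_oni(path)


class TestScheduleSampling:
    def test_short_horizon_cannot_fit_an_event(self, rng):
        sched = rc.draw_schedule(rc.ScheduleConfig(), (2005.0, 2007.0), rng)
        assert len(sched) <= 1

    def test_gaps_and_durations_respect_bounds(self):
        rng = np.random.default_rng(42)
        cfg = rc.ScheduleConfig()
        for _ in range(300):
            sched = rc.draw_schedule(cfg, (2005.0, 2100.0), rng)
            gaps = sched.gaps()
            assert np.all(gaps >= 3.0) and np.all(gaps <= 9.0)
            for ev in sched.events:
                assert 2.0 <= ev.duration_weeks <= 8.0
                assert 2005.0 <= ev.t_start <= 2100.0

    def test_identical_seeds_identical_schedules(self):
        cfg = rc.ScheduleConfig()
        a = rc.draw_schedule(cfg, (2005.0, 2100.0), np.random.default_rng(7))
        b = rc.draw_schedule(cfg, (2005.0, 2100.0), np.random.default_rng(7))
        assert a.events == b.events

    def test_mean_gap_matches_truncated_poisson_enumeration(self):
        """Oracle: the exact pmf of Poisson(6) restricted to {3..9}.

        Only the first start-to-start gap of each schedule enters the mean:
        later gaps are horizon-censored (a schedule drops any gap that would
        overshoot 2100, biasing interior gaps low by the inspection paradox),
        while the first gap is a clean draw from the truncated distribution.
        """
        from scipy import stats

        k = np.arange(3, 10)
        pmf = stats.poisson.pmf(k, 6.0)
        pmf = pmf / pmf.sum()
        expected = float((k * pmf).sum())
        expected_var = float((k**2 * pmf).sum() - expected**2)

        rng = np.random.default_rng(11)
        first_gaps = []
        for _ in range(1500):
            gaps = rc.draw_schedule(rc.ScheduleConfig(), (2005.0, 2100.0), rng).gaps()
            if gaps.size:
                first_gaps.append(gaps[0])
        first_gaps = np.asarray(first_gaps)
        se = np.sqrt(expected_var / first_gaps.size)
        assert abs(first_gaps.mean() - expected) <= 2.0 * se

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            rc.ScheduleConfig(mean_interval=12.0)

    def test_high_frequency_variant(self):
        hf = rc.ScheduleConfig().high_frequency()
        assert (hf.interval_min, hf.interval_max, hf.mean_interval) == (3, 6, 4.5)

    def test_export_round_trip(self, tmp_path, rng):
        import pandas as pd

        sched = rc.draw_schedule(rc.ScheduleConfig(), (2005.0, 2100.0), rng)
        path = tmp_path / "schedule.csv"
        sched.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t_start", "duration_weeks", "eps"]
        assert len(df) == len(sched)
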