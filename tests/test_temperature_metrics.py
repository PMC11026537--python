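"""Temperature QC, daily/weekly aggregation, AHS, MDTF, climatology."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from reefstress import (
    TemperatureSeries,
    accumulated_heat_stress,
    climatology_envelope,
    daily_summaries,
    generate_temperature,
    max_ahs,
    mean_daily_temperature_fluctuation,
    moorea_2019_like,
    qc_continuity,
    weekly_means,
)
from reefstress.temperature_metrics import site_metrics_table

from conftest import make_constant_day_series

TZ = "Etc/GMT+10"
YEAR = (dt.date(2018, 8, 1), dt.date(2019, 7, 31))


def full_year_series(temp=29.5):
    idx = pd.date_range(pd.Timestamp("2018-08-01", tz=TZ),
                        pd.Timestamp("2019-08-01", tz=TZ),
                        freq="20min", inclusive="left")
    return TemperatureSeries(site="S", depth_m=10.0,
                             samples=pd.Series(temp, index=idx))


def brute_force_gaps(series, window, max_gap):
    """Oracle: direct pairwise scan of consecutive timestamps (with window
    sentinels) for gaps exceeding max_gap."""
    t0 = pd.Timestamp(window[0], tz=series.tz)
    t1 = pd.Timestamp(window[1], tz=series.tz) + pd.Timedelta(days=1)
    stamps = [t0] + [t for t in series.clean.index if t0 <= t < t1] + [t1]
    return sum(1 for a, b in zip(stamps, stamps[1:]) if b - a > max_gap)


class TestContinuityQC:
    def test_full_year_is_continuous(self):
        report = qc_continuity(full_year_series(), window=YEAR)
        assert report.continuous and report.gaps == []

    def test_ten_day_hole_is_one_gap(self):
        s = full_year_series()
        hole = (s.samples.index < pd.Timestamp("2019-01-05", tz=TZ)) | \
               (s.samples.index >= pd.Timestamp("2019-01-15", tz=TZ))
        holed = TemperatureSeries(site="S", depth_m=10.0, samples=s.samples[hole])
        report = qc_continuity(holed, window=YEAR)
        assert report.verdict == "discontinuous"
        assert len(report.gaps) == 1
        assert report.gaps[0].duration >= pd.Timedelta(days=10)

    def test_generator_dropout_matches_bruteforce_scan(self):
        dropouts = {("LTER 1", 10.0): ((dt.date(2019, 1, 1), dt.date(2019, 1, 30)),)}
        series = generate_temperature(moorea_2019_like(seed=5, dropouts=dropouts))
        max_gap = pd.Timedelta(hours=6)
        for cell, s in series.items():
            report = qc_continuity(s, window=YEAR, max_gap=max_gap)
            n_oracle = brute_force_gaps(s, YEAR, max_gap)
            assert len(report.gaps) == n_oracle
            assert report.continuous == (n_oracle == 0 and report.completeness >= 0.9)
        assert not qc_continuity(series[("LTER 1", 10.0)], window=YEAR).continuous

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="no samples"):
            qc_continuity(TemperatureSeries("S", 10.0, pd.Series(dtype=float)))

    def test_window_outside_span_is_full_window_gap(self):
        s = make_constant_day_series(start="2017-01-01", n_days=5)
        report = qc_continuity(s, window=YEAR)
        assert report.verdict == "discontinuous"
        assert len(report.gaps) == 1
        assert report.gaps[0].duration == pd.Timedelta(days=365)

    def test_verdict_invariant_to_presort_permutation(self, rng):
        s = full_year_series()
        frame = pd.DataFrame({"t": s.samples.index, "v": s.samples.to_numpy()})
        shuffled = frame.sample(frac=1.0, random_state=1).sort_values("t")
        s2 = TemperatureSeries("S", 10.0,
                               pd.Series(shuffled["v"].to_numpy(),
                                         index=pd.DatetimeIndex(shuffled["t"])))
        assert qc_continuity(s2, window=YEAR).verdict == \
            qc_continuity(s, window=YEAR).verdict


class TestDailySummaries:
    def test_constant_day(self):
        daily = daily_summaries(make_constant_day_series(29.5))
        assert len(daily) == 1
        row = daily.iloc[0]
        assert row["mean_temp"] == pytest.approx(29.5)
        assert row["range"] == pytest.approx(0.0)
        assert row["complete"]

    def test_sinusoid_day_range_matches_sampled_extremes(self):
        idx = pd.date_range(pd.Timestamp("2019-02-01", tz=TZ), periods=72,
                            freq="20min")
        hours = (idx - idx[0]) / pd.Timedelta(hours=1)
        vals = 29.0 + 0.3 * np.sin(2 * np.pi * hours / 24.0)
        s = TemperatureSeries("S", 10.0, pd.Series(vals.to_numpy(), index=idx))
        daily = daily_summaries(s)
        expected = vals.max() - vals.min()  # oracle: extremes on the grid
        assert daily.iloc[0]["range"] == pytest.approx(expected, abs=1e-12)
        assert daily.iloc[0]["range"] == pytest.approx(0.6, abs=0.01)

    def test_sparse_day_incomplete(self):
        idx = pd.date_range(pd.Timestamp("2019-02-01", tz=TZ), periods=10,
                            freq="20min")
        s = TemperatureSeries("S", 10.0, pd.Series(29.0, index=idx))
        assert not daily_summaries(s, completeness=0.8).iloc[0]["complete"]

    def test_range_equals_raw_scan(self):
        series = generate_temperature(moorea_2019_like(seed=2))[("LTER 2", 17.0)]
        daily = daily_summaries(series)
        raw = series.clean
        for date in list(daily.index)[:40]:
            day = raw[np.array([t.date() == date for t in raw.index])]
            assert daily.loc[date, "range"] == pytest.approx(
                day.max() - day.min(), abs=1e-12)

    def test_out_of_band_samples_excluded(self):
        s = make_constant_day_series(29.5)
        samples = s.samples.copy()
        samples.iloc[10] = 55.0  # implausible spike
        flagged = TemperatureSeries("S", 10.0, samples)
        assert flagged.flagged.sum() == 1
        assert daily_summaries(flagged).iloc[0]["max_temp"] == pytest.approx(29.5)


class TestWeeklyMeans:
    def test_constant_week(self):
        daily = daily_summaries(make_constant_day_series(29.5, n_days=7))
        weekly = weekly_means(daily, anchor=dt.date(2019, 2, 1))
        assert weekly.iloc[0]["weekly_mean"] == pytest.approx(29.5)
        assert weekly.iloc[0]["valid"]

    def test_arithmetic_mean_of_daily_means(self):
        daily = daily_summaries(make_constant_day_series(29.0, n_days=7))
        daily["mean_temp"] = [29.0, 29.1, 29.2, 29.3, 29.4, 29.5, 29.6]
        weekly = weekly_means(daily, anchor=dt.date(2019, 2, 1))
        assert weekly.iloc[0]["weekly_mean"] == pytest.approx(29.3)

    def test_three_complete_days_invalid(self):
        daily = daily_summaries(make_constant_day_series(29.5, n_days=7))
        daily.loc[daily.index[3:], "complete"] = False
        weekly = weekly_means(daily, anchor=dt.date(2019, 2, 1))
        assert not weekly.iloc[0]["valid"]
        assert np.isnan(weekly.iloc[0]["weekly_mean"])


class TestAccumulatedHeatStress:
    def test_below_threshold_everywhere_zero(self, weekly_frame):
        ahs = accumulated_heat_stress(weekly_frame([28.0] * 20))
        assert (ahs.table["ahs"] == 0).all()

    def test_constant_half_degree_excess(self, weekly_frame):
        ahs = accumulated_heat_stress(weekly_frame([29.5] * 15))
        full = ahs.table.loc[~ahs.table["warm_up"]]
        assert np.allclose(full["ahs"], 6.0)

    def test_sub_gate_week_contributes_zero(self, weekly_frame):
        ahs = accumulated_heat_stress(weekly_frame([29.2] * 11 + [29.05]))
        assert ahs.table.iloc[-1]["contribution"] == 0.0
        assert ahs.table.iloc[-1]["ahs"] == pytest.approx(11 * 0.2)

    def test_exact_gate_week_contributes(self, weekly_frame):
        ahs = accumulated_heat_stress(weekly_frame([29.1] * 12))
        assert ahs.table.iloc[-1]["ahs"] == pytest.approx(1.2)

    def test_excess_gate_mode(self, weekly_frame):
        ahs = accumulated_heat_stress(weekly_frame([29.5] * 12),
                                      gate_mode="excess")
        assert ahs.table.iloc[-1]["ahs"] == pytest.approx(12 * 0.4)

    def test_strict_gap_policy_undefines_window(self, weekly_frame):
        valid = [True] * 20
        valid[10] = False
        weekly = weekly_frame([29.5] * 20, valid=valid)
        ahs = accumulated_heat_stress(weekly, gap_policy="strict")
        # every window containing week 10 is undefined
        bad = ahs.table.index[(ahs.table.index >= 10) & (ahs.table.index <= 21)]
        assert not ahs.table.loc[bad, "defined"].any()
        lenient = accumulated_heat_stress(weekly, gap_policy="lenient")
        assert lenient.table.loc[19, "ahs"] == pytest.approx(6.0)

    def test_monotone_in_weekly_mean_without_gate(self, weekly_frame, rng):
        base = 28.5 + rng.random(20)
        a0 = accumulated_heat_stress(weekly_frame(base), min_exceedance=0.0)
        bumped = base.copy()
        bumped[7] += 0.5
        a1 = accumulated_heat_stress(weekly_frame(bumped), min_exceedance=0.0)
        assert (a1.table["ahs"] >= a0.table["ahs"] - 1e-12).all()

    def test_max_ahs_simple(self, weekly_frame):
        weekly = weekly_frame([28.0] * 12 + [29.3, 30.0, 29.8] + [28.0] * 5)
        ahs = accumulated_heat_stress(weekly)
        peak = max_ahs(ahs)
        # oracle: best 12-week windowed sum of contributions
        c = ahs.table["contribution"].to_numpy()
        brute = max(c[i - 11:i + 1].sum() for i in range(11, len(c)))
        assert peak.value == pytest.approx(brute)

    def test_max_ahs_undefined_errors(self, weekly_frame):
        weekly = weekly_frame([29.5] * 5)  # warm-up only
        ahs = accumulated_heat_stress(weekly)
        with pytest.raises(ValueError, match="AHS undefined"):
            max_ahs(ahs)

    def test_empty_weekly_errors(self):
        with pytest.raises(ValueError, match="empty"):
            accumulated_heat_stress(pd.DataFrame(columns=["week_start",
                                                          "weekly_mean", "valid"]))


class TestMDTF:
    def test_constant_series_zero(self):
        daily = daily_summaries(make_constant_day_series(29.5, n_days=10,
                                                         start="2019-02-15"))
        r = mean_daily_temperature_fluctuation(
            daily, window=(dt.date(2019, 2, 15), dt.date(2019, 2, 24)))
        assert r.mdtf == pytest.approx(0.0)
        assert r.n_days_used == 10

    def test_fixed_daily_range(self):
        daily = daily_summaries(make_constant_day_series(29.5, n_days=5,
                                                         start="2019-02-15"))
        daily["range"] = 0.4
        r = mean_daily_temperature_fluctuation(
            daily, window=(dt.date(2019, 2, 15), dt.date(2019, 2, 19)))
        assert r.mdtf == pytest.approx(0.4)

    def test_offset_invariance_and_scaling(self):
        idx = pd.date_range(pd.Timestamp("2019-02-15", tz=TZ), periods=72 * 6,
                            freq="20min")
        hours = np.arange(len(idx)) / 3.0
        base = 29.0 + 0.2 * np.sin(2 * np.pi * hours / 24.0)
        window = (dt.date(2019, 2, 15), dt.date(2019, 2, 20))
        def mdtf_of(vals):
            s = TemperatureSeries("S", 10.0, pd.Series(vals, index=idx))
            return mean_daily_temperature_fluctuation(
                daily_summaries(s), window=window).mdtf
        m = mdtf_of(base)
        assert mdtf_of(base + 1.7) == pytest.approx(m, abs=1e-12)
        assert mdtf_of(29.0 + 3.0 * (base - 29.0)) == pytest.approx(3 * m, rel=1e-9)

    def test_no_complete_days_errors(self):
        daily = daily_summaries(make_constant_day_series(29.5, n_days=3,
                                                         start="2019-02-15"))
        daily["complete"] = False
        with pytest.raises(ValueError, match="no complete days"):
            mean_daily_temperature_fluctuation(
                daily, window=(dt.date(2019, 2, 15), dt.date(2019, 2, 17)))


class TestClimatology:
    @staticmethod
    def _multi_year_daily(years, value_fn):
        frames = []
        for y in years:
            idx = pd.date_range(pd.Timestamp(f"{y}-01-01", tz=TZ),
                                pd.Timestamp(f"{y+1}-01-01", tz=TZ),
                                freq="6h", inclusive="left")
            s = TemperatureSeries("S", 10.0,
                                  pd.Series(value_fn(y), index=idx),
                                  nominal_interval=pd.Timedelta(hours=6))
            frames.append(daily_summaries(s, completeness=0.5))
        return pd.concat(frames)

    def test_identical_years_zero_width(self):
        daily = self._multi_year_daily([2005, 2006, 2007], lambda y: 28.0)
        env = climatology_envelope(daily, reference_years=[2005, 2006, 2007])
        assert np.allclose(env["mean_temp"], 28.0)
        assert np.allclose(env["ci95_low"], env["ci95_high"])

    def test_two_point_t_interval(self):
        daily = self._multi_year_daily([2005, 2006],
                                       lambda y: 28.0 if y == 2005 else 30.0)
        env = climatology_envelope(daily, reference_years=[2005, 2006])
        row = env.iloc[100]
        # oracle: closed-form two-point t interval, SE = sqrt(2)/sqrt(2) = 1
        from scipy import stats
        assert row["mean_temp"] == pytest.approx(29.0)
        half = stats.t.ppf(0.975, 1) * 1.0
        assert row["ci95_high"] - row["mean_temp"] == pytest.approx(half, rel=1e-9)

    def test_feb29_merged(self):
        daily = self._multi_year_daily([2007, 2008], lambda y: 28.0)  # 2008 leap
        env = climatology_envelope(daily, reference_years=[2007, 2008])
        assert len(env) == 365
        assert (env["n_years"] == 2).all()

    def test_single_year_errors(self):
        daily = self._multi_year_daily([2005], lambda y: 28.0)
        with pytest.raises(ValueError, match="two reference years"):
            climatology_envelope(daily, reference_years=[2005])


class TestSiteMetricsTable:
    def test_dropout_cell_excluded(self):
        dropouts = {("LTER 4", 10.0): ((dt.date(2018, 12, 1), dt.date(2019, 1, 15)),)}
        series = generate_temperature(moorea_2019_like(seed=3, dropouts=dropouts))
        summary, excluded = site_metrics_table(series)
        assert ("LTER 4", 10.0) in {(s, d) for s, d, _ in excluded}
        assert len(summary) == 7
        assert not ((summary["site"] == "LTER 4") & (summary["depth_m"] == 10.0)).any()
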