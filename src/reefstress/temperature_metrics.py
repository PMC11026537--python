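"""Thermal-stress metrics from in situ benthic temperature-logger series.

This module turns high-frequency (nominally 20-minute) temperature records
from bottom-mounted thermistors into the two statistics used to explain
spatial variation in coral bleaching:

* **Accumulated Heat Stress (AHS, °C-weeks)** — a 12-week running sum of
  weekly mean temperatures exceeding the local Maximum Monthly Mean
  (MMM, 29.0 °C for Moorea) by at least 0.1 °C.  A week whose mean is below
  the 29.1 °C qualification gate contributes nothing; a qualifying week
  contributes its full excess above the MMM.
* **Mean Daily Temperature Fluctuation (MDTF, °C)** — the mean daily
  temperature range (daily max − min) over a window, by default the month
  before bleaching onset (15 Feb – 15 Mar 2019).

It also provides logger quality control (gap detection over an analysis
window, mirroring the exclusion of loggers without continuous data through
the bleaching year), daily summaries, weekly means, and a multi-year
day-of-year climatology envelope.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("reefstress.temperature")

# ---------------------------------------------------------------------------
# Defaults (all overridable per call; see pipeline.RunConfig)
# ---------------------------------------------------------------------------

#: Local time for Moorea / Tahiti (UTC-10, no DST).
DEFAULT_TZ = "Etc/GMT+10"

#: Maximum Monthly Mean bleaching threshold for Moorea, °C.
MMM_C = 29.0

#: Minimum weekly exceedance for a week to count toward AHS, °C.
MIN_EXCEEDANCE_C = 0.1

#: Length of the AHS running-sum window, weeks.
AHS_WINDOW_WEEKS = 12

#: Analysis year for bleaching: 1 Aug 2018 – 31 Jul 2019 (inclusive).
BLEACHING_YEAR = (dt.date(2018, 8, 1), dt.date(2019, 7, 31))

#: MDTF window: the month before first observed bleaching (inclusive).
MDTF_WINDOW = (dt.date(2019, 2, 15), dt.date(2019, 3, 15))

#: A day is "complete" when it has at least this fraction of expected samples.
DAY_COMPLETENESS = 0.8

#: A week is valid when at least this fraction of its 7 days is complete.
WEEK_VALID_FRACTION = 6 / 7

#: Plausibility band for raw logger temperatures, °C; outside -> flagged.
PLAUSIBLE_BAND_C = (20.0, 35.0)

#: Nominal sampling interval of the loggers.
NOMINAL_INTERVAL = pd.Timedelta(minutes=20)

#: Depth labels: loggers nominally at 20 m are analysed as the 17 m isobath.
DEPTH_ALIASES = {20.0: 17.0}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TemperatureSeries:
    """Timestamped temperature samples for one site x depth logger.

    ``samples`` is a float Series indexed by a strictly increasing,
    timezone-aware DatetimeIndex.  Samples outside ``plausible_band`` are
    flagged (``flagged`` mask) and excluded from all derived statistics, not
    dropped from the record.
    """

    site: str
    depth_m: float
    samples: pd.Series
    nominal_interval: pd.Timedelta = NOMINAL_INTERVAL
    plausible_band: tuple[float, float] = PLAUSIBLE_BAND_C
    tz: str = DEFAULT_TZ
    flagged: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = pd.Series(self.samples, dtype=float)
        idx = pd.DatetimeIndex(s.index)
        if idx.tz is None:
            idx = idx.tz_localize(self.tz)
        else:
            idx = idx.tz_convert(self.tz)
        s.index = idx
        if len(s) and not s.index.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(s) and (np.diff(s.index.asi8) <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        self.samples = s
        lo, hi = self.plausible_band
        self.flagged = ~s.between(lo, hi)
        n_bad = int(self.flagged.sum())
        if n_bad:
            logger.info(
                "%s %gm: flagged %d sample(s) outside plausibility band %s",
                self.site, self.depth_m, n_bad, self.plausible_band,
            )

    @property
    def clean(self) -> pd.Series:
        """Samples with out-of-band values removed."""
        return self.samples[~self.flagged]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Gap:
    """A data gap inside an analysis window."""

    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


@dataclass
class ContinuityReport:
    """Verdict of the continuity QC for one logger over a window."""

    site: str
    depth_m: float
    verdict: str  # "continuous" | "discontinuous"
    gaps: list[Gap]
    n_samples: int
    expected_samples: float
    completeness: float

    @property
    def continuous(self) -> bool:
        return self.verdict == "continuous"


@dataclass
class AHSSeries:
    """Weekly accumulated-heat-stress trajectory.

    ``table`` has one row per week: week_start, weekly_mean, contribution,
    ahs (NaN where undefined under the gap policy), warm_up (fewer than
    ``window_weeks`` predecessors), defined.
    """

    table: pd.DataFrame
    threshold_mmm: float
    min_exceedance: float
    window_weeks: int
    gate_mode: str
    gap_policy: str

    def max_ahs(self, window: tuple[dt.date, dt.date] | None = None,
                include_warmup: bool = False) -> "MaxAHS":
        return max_ahs(self, window=window, include_warmup=include_warmup)


@dataclass(frozen=True)
class MaxAHS:
    value: float
    week_start: dt.date


@dataclass(frozen=True)
class MDTFResult:
    """Mean daily temperature fluctuation over a window (inclusive)."""

    window_start: dt.date
    window_end: dt.date
    mdtf: float
    n_days_used: int


# ---------------------------------------------------------------------------
# CSV ingest
# ---------------------------------------------------------------------------

def read_temperature_csv(path, tz: str = DEFAULT_TZ,
                         nominal_interval: pd.Timedelta = NOMINAL_INTERVAL,
                         depth_aliases: Mapping[float, float] = DEPTH_ALIASES,
                         ) -> dict[tuple[str, float], TemperatureSeries]:
    """Read a long-format logger CSV into per site x depth series.

    Expected columns: ``timestamp`` (ISO 8601, offset honoured), ``site``,
    ``depth_m``, ``temp_c``.  Depths listed in ``depth_aliases`` (by default
    the 20 m deployment depth) are relabelled to their analysis isobath
    (17 m) at ingest.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "site", "depth_m", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"temperature CSV missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df = df.assign(timestamp=ts.dt.tz_convert(tz))
    df["depth_m"] = df["depth_m"].astype(float).replace(dict(depth_aliases))
    out: dict[tuple[str, float], TemperatureSeries] = {}
    for (site, depth), grp in df.groupby(["site", "depth_m"], sort=True):
        grp = grp.sort_values("timestamp")
        samples = pd.Series(grp["temp_c"].to_numpy(), index=pd.DatetimeIndex(grp["timestamp"]))
        out[(str(site), float(depth))] = TemperatureSeries(
            site=str(site), depth_m=float(depth), samples=samples,
            nominal_interval=nominal_interval, tz=tz,
        )
    return out


def _window_bounds(window: tuple[dt.date, dt.date], tz: str) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Inclusive date window -> half-open [start 00:00, end+1d 00:00) timestamps."""
    start, end = window
    t0 = pd.Timestamp(start, tz=tz)
    t1 = pd.Timestamp(end, tz=tz) + pd.Timedelta(days=1)
    if t1 <= t0:
        raise ValueError("window is empty")
    return t0, t1


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_continuity(series: TemperatureSeries,
                  window: tuple[dt.date, dt.date] = BLEACHING_YEAR,
                  max_gap: pd.Timedelta = pd.Timedelta(hours=6),
                  completeness: float = 0.9) -> ContinuityReport:
    """Classify a logger as continuous or discontinuous over a window.

    A logger is discontinuous when any gap between consecutive samples inside
    the window (including the leads from the window edges to the first/last
    sample) exceeds ``max_gap``, or when the total sample count falls below
    ``completeness`` x expected.  Mirrors the exclusion of loggers that failed
    to record continuously through the bleaching year.
    """
    if len(series) == 0:
        raise ValueError("no samples")
    if max_gap <= series.nominal_interval:
        raise ValueError("max_gap must exceed the nominal sampling interval")
    t0, t1 = _window_bounds(window, series.tz)
    idx = series.clean.index
    inside = idx[(idx >= t0) & (idx < t1)]
    expected = (t1 - t0) / series.nominal_interval
    gaps: list[Gap] = []
    if len(inside) == 0:
        gaps.append(Gap(t0, t1))
    else:
        points = inside.insert(0, t0).append(pd.DatetimeIndex([t1]))
        deltas = np.diff(points.asi8)
        bad = np.flatnonzero(deltas > max_gap.value)
        for i in bad:
            gaps.append(Gap(points[i], points[i + 1]))
    frac = len(inside) / expected
    verdict = "continuous"
    if gaps or frac < completeness:
        verdict = "discontinuous"
    report = ContinuityReport(
        site=series.site, depth_m=series.depth_m, verdict=verdict,
        gaps=gaps, n_samples=len(inside), expected_samples=float(expected),
        completeness=float(frac),
    )
    logger.info(
        "QC %s %gm: %s (%d gaps > %s, %.1f%% of expected samples)",
        series.site, series.depth_m, verdict, len(gaps), max_gap, 100 * frac,
    )
    return report


# ---------------------------------------------------------------------------
# Daily and weekly aggregation
# ---------------------------------------------------------------------------

def daily_summaries(series: TemperatureSeries,
                    completeness: float = DAY_COMPLETENESS) -> pd.DataFrame:
    """Per-local-calendar-day mean/min/max/range summaries.

    Returns a frame indexed by date with columns mean_temp, min_temp,
    max_temp, range, n_samples, complete.  Days are local (UTC-10 by
    default) so the diurnal cycle does not straddle midnight; ``complete``
    requires at least ``completeness`` of the samples expected at the nominal
    interval.
    """
    s = series.clean
    if s.empty:
        raise ValueError("no samples")
    expected_per_day = pd.Timedelta(days=1) / series.nominal_interval
    grouped = s.groupby(s.index.date)
    out = grouped.agg(mean_temp="mean", min_temp="min", max_temp="max",
                      n_samples="size")
    out["range"] = out["max_temp"] - out["min_temp"]
    out["complete"] = out["n_samples"] >= completeness * expected_per_day
    out.index = pd.Index(out.index, name="date")
    return out[["mean_temp", "min_temp", "max_temp", "range", "n_samples", "complete"]]


def weekly_means(daily: pd.DataFrame, anchor: dt.date = BLEACHING_YEAR[0],
                 valid_fraction: float = WEEK_VALID_FRACTION) -> pd.DataFrame:
    """Means over consecutive 7-day blocks anchored at ``anchor``.

    Weeks are calendar-convention-free: block k covers
    [anchor + 7k, anchor + 7k + 6].  The block mean uses complete days only
    and a block is valid when its complete-day fraction reaches
    ``valid_fraction`` (default 6 of 7).  Invalid blocks carry NaN.
    Blocks before ``anchor`` are not produced.
    """
    if daily.empty:
        raise ValueError("no daily summaries")
    dates = pd.Index(daily.index)
    offsets = np.array([(d - anchor).days for d in dates])
    keep = offsets >= 0
    if not keep.any():
        raise ValueError("no daily summaries on or after the anchor")
    block = offsets[keep] // 7
    sub = daily.loc[keep]
    rows = []
    for b in range(int(block.max()) + 1):
        in_block = sub.loc[block == b]
        comp = in_block.loc[in_block["complete"]]
        n_complete = len(comp)
        valid = n_complete >= valid_fraction * 7 - 1e-9
        rows.append({
            "week_start": anchor + dt.timedelta(days=7 * b),
            "weekly_mean": comp["mean_temp"].mean() if valid else np.nan,
            "n_complete_days": n_complete,
            "valid": bool(valid),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Accumulated heat stress
# ---------------------------------------------------------------------------

def accumulated_heat_stress(weekly: pd.DataFrame,
                            mmm: float = MMM_C,
                            min_exceedance: float = MIN_EXCEEDANCE_C,
                            window_weeks: int = AHS_WINDOW_WEEKS,
                            gate_mode: str = "qualify",
                            gap_policy: str = "strict") -> AHSSeries:
    """12-week running sum of qualifying weekly exceedances above the MMM.

    A week with mean >= ``mmm + min_exceedance`` contributes its excess above
    the threshold; cooler weeks contribute 0.  Two readings of the
    contribution are supported:

    * ``gate_mode="qualify"`` (default): the 0.1 °C is a qualification gate
      and a qualifying week contributes ``weekly_mean - mmm`` (the full
      hotspot magnitude above 29.0 °C).
    * ``gate_mode="excess"``: a qualifying week contributes
      ``weekly_mean - (mmm + min_exceedance)``.

    ``gap_policy="strict"`` leaves ahs undefined (NaN) whenever any of the
    window's weeks is invalid; ``"lenient"`` averages the valid weeks and
    rescales by ``window_weeks / n_valid``.  Weeks with fewer than
    ``window_weeks`` predecessors are flagged ``warm_up`` and carry the
    partial sum.
    """
    if weekly.empty:
        raise ValueError("empty weekly series")
    if gate_mode not in ("qualify", "excess"):
        raise ValueError(f"unknown gate_mode {gate_mode!r}")
    if gap_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    wm = weekly["weekly_mean"].to_numpy(dtype=float)
    valid = weekly["valid"].to_numpy(dtype=bool) & np.isfinite(wm)
    contrib = np.zeros_like(wm)
    qualifies = valid & (wm >= mmm + min_exceedance - 1e-12)
    base = mmm if gate_mode == "qualify" else mmm + min_exceedance
    contrib[qualifies] = wm[qualifies] - base
    contrib[~valid] = np.nan

    n = len(wm)
    ahs = np.full(n, np.nan)
    warm_up = np.zeros(n, dtype=bool)
    for w in range(n):
        lo = max(0, w - window_weeks + 1)
        c = contrib[lo:w + 1]
        warm_up[w] = (w - lo + 1) < window_weeks
        bad = ~np.isfinite(c)
        if not bad.any():
            ahs[w] = c.sum()
        elif gap_policy == "lenient" and (~bad).any():
            ahs[w] = c[~bad].sum() * len(c) / (~bad).sum()
        # strict with any invalid week: leave NaN (undefined)
    table = pd.DataFrame({
        "week_start": weekly["week_start"].to_numpy(),
        "weekly_mean": wm,
        "contribution": contrib,
        "ahs": ahs,
        "warm_up": warm_up,
        "defined": np.isfinite(ahs),
    })
    return AHSSeries(table=table, threshold_mmm=mmm,
                     min_exceedance=min_exceedance,
                     window_weeks=window_weeks, gate_mode=gate_mode,
                     gap_policy=gap_policy)


def max_ahs(ahs: AHSSeries, window: tuple[dt.date, dt.date] | None = None,
            include_warmup: bool = False) -> MaxAHS:
    """Maximum defined AHS value (with its week) inside a date window.

    Warm-up weeks (partial windows) are excluded by default so a record that
    starts mid-heatwave cannot report a spuriously low running sum as its
    maximum.
    """
    t = ahs.table
    mask = t["defined"].to_numpy(copy=True)
    if not include_warmup:
        mask &= ~t["warm_up"].to_numpy()
    if window is not None:
        ws = pd.Index(t["week_start"])
        mask &= (ws >= window[0]) & (ws <= window[1])
    if not mask.any():
        raise ValueError("AHS undefined in window")
    sub = t.loc[mask]
    i = sub["ahs"].idxmax()
    return MaxAHS(value=float(t.loc[i, "ahs"]), week_start=t.loc[i, "week_start"])


# ---------------------------------------------------------------------------
# Mean daily temperature fluctuation
# ---------------------------------------------------------------------------

def mean_daily_temperature_fluctuation(daily: pd.DataFrame,
                                       window: tuple[dt.date, dt.date] = MDTF_WINDOW,
                                       ) -> MDTFResult:
    """Mean of the daily temperature range over an inclusive date window.

    Only complete days contribute; a window with no complete day is an
    error rather than a silent zero.
    """
    start, end = window
    if end < start:
        raise ValueError("window is empty")
    dates = pd.Index(daily.index)
    in_win = (dates >= start) & (dates <= end)
    sub = daily.loc[in_win & daily["complete"].to_numpy()]
    if sub.empty:
        raise ValueError("no complete days in MDTF window")
    return MDTFResult(window_start=start, window_end=end,
                      mdtf=float(sub["range"].mean()), n_days_used=len(sub))


# ---------------------------------------------------------------------------
# Multi-year climatology
# ---------------------------------------------------------------------------

def climatology_envelope(daily: pd.DataFrame,
                         reference_years: Iterable[int] = range(2005, 2019),
                         ) -> pd.DataFrame:
    """Day-of-year mean and 95% CI of daily mean temperature across years.

    Uses a 365-day index; 29 February is merged into 28 February.  The CI is
    the t-interval on the across-year SD, reported only for days with at
    least two contributing years.
    """
    years = set(int(y) for y in reference_years)
    dates = pd.Index(daily.index)
    keep = np.array([d.year in years for d in dates])
    sub = daily.loc[keep & daily["complete"].to_numpy()]
    if sub.empty:
        raise ValueError("no complete days in the reference years")

    def doy365(d: dt.date) -> int:
        if d.month == 2 and d.day == 29:
            d = d.replace(day=28)
        return dt.date(2001, d.month, d.day).timetuple().tm_yday

    frame = pd.DataFrame({
        "doy": [doy365(d) for d in sub.index],
        "year": [d.year for d in sub.index],
        "mean_temp": sub["mean_temp"].to_numpy(),
    })
    # Feb-29 merge can give a year two entries on doy 59 -> average per year first.
    per_year = frame.groupby(["doy", "year"])["mean_temp"].mean().reset_index()
    g = per_year.groupby("doy")["mean_temp"]
    out = g.agg(mean_temp="mean", sd="std", n_years="size").reset_index()
    if (out["n_years"] < 2).all():
        raise ValueError("fewer than two reference years everywhere")
    se = out["sd"] / np.sqrt(out["n_years"])
    tq = stats.t.ppf(0.975, out["n_years"] - 1)
    ok = out["n_years"] >= 2
    out["ci95_low"] = np.where(ok, out["mean_temp"] - tq * se, np.nan)
    out["ci95_high"] = np.where(ok, out["mean_temp"] + tq * se, np.nan)
    return out[["doy", "mean_temp", "ci95_low", "ci95_high", "n_years"]]


# ---------------------------------------------------------------------------
# Site-level convenience
# ---------------------------------------------------------------------------

def site_metrics_table(series_by_cell: Mapping[tuple[str, float], TemperatureSeries],
                       bleaching_year: tuple[dt.date, dt.date] = BLEACHING_YEAR,
                       mdtf_window: tuple[dt.date, dt.date] = MDTF_WINDOW,
                       mmm: float = MMM_C,
                       min_exceedance: float = MIN_EXCEEDANCE_C,
                       window_weeks: int = AHS_WINDOW_WEEKS,
                       max_gap: pd.Timedelta = pd.Timedelta(hours=6),
                       qc_completeness: float = 0.9,
                       day_completeness: float = DAY_COMPLETENESS,
                       gate_mode: str = "qualify",
                       gap_policy: str = "strict",
                       ) -> tuple[pd.DataFrame, list[tuple[str, float, str]]]:
    """QC every logger and compute max AHS + MDTF per continuous cell.

    Returns a summary frame (site, depth_m, max_ahs_c_weeks, mdtf_c,
    mdtf_days, mean_daily_temp_c) for the cells that pass continuity QC over
    the bleaching year, plus a list of excluded (site, depth, reason) cells.
    """
    rows = []
    excluded: list[tuple[str, float, str]] = []
    for (site, depth), series in sorted(series_by_cell.items()):
        report = qc_continuity(series, window=bleaching_year, max_gap=max_gap,
                               completeness=qc_completeness)
        if not report.continuous:
            excluded.append((site, depth, f"discontinuous ({len(report.gaps)} gaps)"))
            continue
        daily = daily_summaries(series, completeness=day_completeness)
        weekly = weekly_means(daily, anchor=bleaching_year[0])
        ahs = accumulated_heat_stress(weekly, mmm=mmm,
                                      min_exceedance=min_exceedance,
                                      window_weeks=window_weeks,
                                      gate_mode=gate_mode, gap_policy=gap_policy)
        peak = max_ahs(ahs, window=bleaching_year)
        mdtf = mean_daily_temperature_fluctuation(daily, window=mdtf_window)
        in_year = (pd.Index(daily.index) >= bleaching_year[0]) & \
                  (pd.Index(daily.index) <= bleaching_year[1])
        year_daily = daily.loc[in_year & daily["complete"].to_numpy()]
        rows.append({
            "site": site, "depth_m": depth,
            "max_ahs_c_weeks": peak.value,
            "mdtf_c": mdtf.mdtf, "mdtf_days": mdtf.n_days_used,
            "mean_daily_temp_c": float(year_daily["mean_temp"].mean()),
        })
    return pd.DataFrame(rows), excluded
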