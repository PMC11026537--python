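"""Synthetic temperature-logger series and colony surveys.

Every pipeline stage and the calibration suites run on data from this
module, so it is first-class, tested code rather than a throwaway fixture.
Three generators:

* ``generate_temperature`` — 20-minute logger series per site x depth built
  from an annual seasonal sinusoid, a diurnal cycle (larger at 10 m), a
  bounded AR(1) high-frequency oscillation (larger at 17 m, standing in
  statistically for internal-wave variability), a marine-heatwave anomaly
  (raised-cosine ramp), measurement noise, and configurable dropout gaps.
* ``generate_survey`` — colony records whose severe-bleaching indicator is
  Bernoulli on a logit-linear predictor in size class, depth, heat stress,
  size x heat-stress interaction, and a Gaussian site intercept; severe
  colonies receive a bleached/dead composition summing with healthy to 100%.
* ``generate_severity_table`` — cell-level percent-severe tables drawn from
  the linear mixed model's own generative form (Gaussian site intercepts
  and residuals on the percent scale), used for parameter-recovery and
  type-I-error calibration of the LMM where exact truth on the percent
  scale is required.

``fixture_table1`` returns the published per site x depth maximum AHS and
MDTF values used as model inputs and for the depth t-tests.

All generators are reproducible bit-for-bit from (scenario, seed).
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .temperature_metrics import (
    BLEACHING_YEAR, DEFAULT_TZ, NOMINAL_INTERVAL, TemperatureSeries,
)

logger = logging.getLogger("reefstress.synthetic")

SIZE_LEVELS = ("small", "mid", "large")


# ---------------------------------------------------------------------------
# Published per-cell metrics (model inputs)
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    ("LTER 1", 10.0, 6.06, 0.45),
    ("LTER 1", 17.0, 5.24, 0.59),
    ("LTER 2", 17.0, 4.85, 0.67),
    ("LTER 4", 10.0, 4.59, 0.41),
    ("LTER 4", 17.0, 4.13, 0.56),
    ("LTER 5", 10.0, 5.17, 0.29),
    ("LTER 5", 17.0, 4.62, 0.39),
    ("LTER 6", 10.0, 5.47, 0.39),
]


def fixture_table1() -> pd.DataFrame:
    """Per site x depth maximum AHS (°C-weeks) and MDTF (°C).

    The eight site x depth cells with continuous logger data through the
    bleaching year (four at each depth); the remaining four loggers failed
    and their cells are absent by design.
    """
    return pd.DataFrame(_TABLE1_ROWS,
                        columns=["site", "depth_m", "max_ahs_c_weeks", "mdtf_c"])


def table1_ahs_lookup() -> dict[tuple[str, float], float]:
    """(site, depth) -> max AHS from the published table."""
    t = fixture_table1()
    return {(r.site, r.depth_m): r.max_ahs_c_weeks for r in t.itertuples()}


# ---------------------------------------------------------------------------
# Temperature generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTemperatureConfig:
    """Per site x depth ingredients of the synthetic logger series."""

    site: str
    depth_m: float
    seasonal_mean: float = 27.7        # °C, annual mean level
    seasonal_amp: float = 1.2          # °C, annual half-range
    seasonal_peak_doy: int = 63        # warmest day of year (early March)
    diurnal_amp: float = 0.15          # °C, half-range of the diurnal cycle
    hf_sd: float = 0.08                # °C, SD of the AR(1) oscillation
    hf_timescale_h: float = 3.0        # hours, AR(1) decorrelation time
    heatwave_start: dt.date = dt.date(2018, 11, 15)
    heatwave_end: dt.date = dt.date(2019, 5, 20)
    heatwave_peak: float = 1.15        # °C, peak anomaly (raised cosine)
    noise_sd: float = 0.01             # °C, instrument noise
    dropouts: tuple[tuple[dt.date, dt.date], ...] = ()


@dataclass(frozen=True)
class TemperatureScenario:
    cells: tuple[CellTemperatureConfig, ...]
    span: tuple[dt.date, dt.date] = BLEACHING_YEAR
    interval: pd.Timedelta = NOMINAL_INTERVAL
    tz: str = DEFAULT_TZ
    seed: int = 0


def _raised_cosine(frac: np.ndarray) -> np.ndarray:
    """0 -> 0, 0.5 -> 1, 1 -> 0; zero outside [0, 1]."""
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * frac))
    out[(frac < 0) | (frac > 1)] = 0.0
    return out


def _cell_temperature(cfg: CellTemperatureConfig, scenario: TemperatureScenario,
                      rng: np.random.Generator) -> TemperatureSeries:
    t0 = pd.Timestamp(scenario.span[0], tz=scenario.tz)
    t1 = pd.Timestamp(scenario.span[1], tz=scenario.tz) + pd.Timedelta(days=1)
    idx = pd.date_range(t0, t1, freq=scenario.interval, inclusive="left")
    doy = idx.dayofyear.to_numpy(dtype=float)
    seasonal = cfg.seasonal_mean + cfg.seasonal_amp * np.cos(
        2 * np.pi * (doy - cfg.seasonal_peak_doy) / 365.25)
    hours = (idx.hour + idx.minute / 60.0).to_numpy(dtype=float)
    diurnal = cfg.diurnal_amp * np.sin(2 * np.pi * hours / 24.0)
    hw_t0 = pd.Timestamp(cfg.heatwave_start, tz=scenario.tz)
    hw_t1 = pd.Timestamp(cfg.heatwave_end, tz=scenario.tz)
    frac = (idx - hw_t0) / (hw_t1 - hw_t0)
    heatwave = cfg.heatwave_peak * _raised_cosine(np.asarray(frac, dtype=float))
    n = len(idx)
    if cfg.hf_sd > 0:
        dt_h = scenario.interval / pd.Timedelta(hours=1)
        phi = np.exp(-dt_h / cfg.hf_timescale_h)
        innov = rng.normal(0.0, cfg.hf_sd * np.sqrt(1 - phi ** 2), size=n)
        hf = np.empty(n)
        hf[0] = rng.normal(0.0, cfg.hf_sd)
        for i in range(1, n):
            hf[i] = phi * hf[i - 1] + innov[i]
        hf = np.clip(hf, -4 * cfg.hf_sd, 4 * cfg.hf_sd)  # bounded oscillation
    else:
        hf = np.zeros(n)
    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
    temp = seasonal + diurnal + heatwave + hf + noise
    samples = pd.Series(temp, index=idx)
    for start, end in cfg.dropouts:
        if end < start:
            raise ValueError(f"dropout {start}..{end} ends before it starts")
        d0 = pd.Timestamp(start, tz=scenario.tz)
        d1 = pd.Timestamp(end, tz=scenario.tz) + pd.Timedelta(days=1)
        samples = samples[(samples.index < d0) | (samples.index >= d1)]
    return TemperatureSeries(site=cfg.site, depth_m=cfg.depth_m,
                             samples=samples,
                             nominal_interval=scenario.interval,
                             tz=scenario.tz)


def generate_temperature(scenario: TemperatureScenario,
                         ) -> dict[tuple[str, float], TemperatureSeries]:
    """Generate one logger series per configured site x depth cell.

    Each cell gets an independent child RNG stream derived from the
    scenario seed and the cell's position, so adding or removing a cell does
    not perturb the others.
    """
    out: dict[tuple[str, float], TemperatureSeries] = {}
    for i, cfg in enumerate(scenario.cells):
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(
            len(scenario.cells))[i])
        out[(cfg.site, cfg.depth_m)] = _cell_temperature(cfg, scenario, rng)
    return out


# Heatwave peaks calibrated (deterministic components only) so each cell's
# realized maximum AHS tracks its published value; high-frequency SD and
# diurnal amplitude give the deeper isobath the larger MDTF.
_MOOREA_PEAKS = {
    ("LTER 1", 10.0): 0.8647, ("LTER 1", 17.0): 0.7867,
    ("LTER 2", 17.0): 0.7454, ("LTER 4", 10.0): 0.7178,
    ("LTER 4", 17.0): 0.6691, ("LTER 5", 10.0): 0.7792,
    ("LTER 5", 17.0): 0.7210, ("LTER 6", 10.0): 0.8110,
}


def moorea_2019_like(seed: int = 0,
                     dropouts: Mapping[tuple[str, float], tuple] | None = None,
                     ) -> TemperatureScenario:
    """Bleaching-year scenario shaped like the 2019 Moorea heatwave.

    Eight site x depth cells (the ones with continuous data); shallow cells
    get the larger diurnal amplitude, deep cells the larger high-frequency
    fluctuation, and per-cell heatwave peaks span maximum AHS values across
    roughly the published 4.1-6.1 °C-weeks range.  ``dropouts`` can inject
    gaps per cell to exercise the continuity QC.
    """
    cells = []
    for (site, depth), peak in _MOOREA_PEAKS.items():
        shallow = depth == 10.0
        cells.append(CellTemperatureConfig(
            site=site, depth_m=depth,
            diurnal_amp=0.16 if shallow else 0.06,
            hf_sd=0.06 if shallow else 0.18,
            heatwave_peak=peak,
            dropouts=tuple((dropouts or {}).get((site, depth), ())),
        ))
    return TemperatureScenario(cells=tuple(cells), seed=seed)


# ---------------------------------------------------------------------------
# Colony-survey generator (logit scale)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenusEffects:
    """Logit-scale generating coefficients for one genus."""

    intercept: float
    size: tuple[float, float, float] = (0.0, 0.0, 0.0)       # small, mid, large
    depth17: float = 0.0
    ahs_slope: float = 0.0
    size_ahs: tuple[float, float, float] = (0.0, 0.0, 0.0)   # per-size AHS slopes


@dataclass(frozen=True)
class BleachingScenario:
    """Colony-level generating model for the bleaching survey."""

    genus_effects: Mapping[str, GenusEffects]
    counts: Mapping[tuple[str, float, str], int]  # (site, depth, genus) -> n
    site_sd: float = 0.3
    size_mixture: tuple[float, float, float] = (0.3, 0.5, 0.2)
    seed: int = 0

    def with_counts_scaled(self, factor: float) -> "BleachingScenario":
        scaled = {k: max(1, int(round(v * factor))) for k, v in self.counts.items()}
        return replace(self, counts=scaled)


def allocate_counts(total: int, cells: list[tuple[str, float]]) -> dict:
    """Split a genus total across cells as evenly as integers allow."""
    base = total // len(cells)
    rem = total - base * len(cells)
    return {cell: base + (1 if i < rem else 0)
            for i, cell in enumerate(sorted(cells))}


def _severity_composition(severe: bool, rng: np.random.Generator):
    """Bleached/dead/healthy percentages consistent with the severity flag.

    Severe colonies draw bleached+dead uniformly on [75, 100] and split off
    up to 30% of it as recently dead; non-severe colonies draw the total
    uniformly on [0, 74.5].  Only the >= 75 boundary matters downstream.
    """
    total = rng.uniform(75.0, 100.0) if severe else rng.uniform(0.0, 74.5)
    dead = total * rng.uniform(0.0, 0.3)
    bleached = total - dead
    return round(100.0 - total, 4), round(bleached, 4), round(dead, 4)


def generate_survey(scenario: BleachingScenario,
                    ahs_lookup: Mapping[tuple[str, float], float],
                    seed: int | None = None) -> pd.DataFrame:
    """Draw a colony table from the scenario's logit-linear model.

    Severity per colony is Bernoulli(expit(eta)) with
    eta = intercept + size effect + depth effect + (ahs_slope + size
    interaction slope) * centered AHS + site intercept; AHS is centered on
    the mean over the lookup's cells.  Colony counts per cell match the
    configuration exactly; transects alternate within each cell.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    cells = sorted(scenario.counts)
    missing = [(s, d) for s, d, _ in cells if (s, d) not in ahs_lookup]
    if missing:
        raise ValueError(f"ahs_lookup missing cells: {sorted(set(missing))}")
    ahs_center = float(np.mean(list(ahs_lookup.values())))
    sites = sorted({s for s, _, _ in cells})
    site_b = dict(zip(sites, rng.normal(0.0, scenario.site_sd, size=len(sites))))
    rows = []
    colony_id = 0
    for site, depth, genus in cells:
        n = scenario.counts[(site, depth, genus)]
        eff = scenario.genus_effects[genus]
        ahs_c = ahs_lookup[(site, depth)] - ahs_center
        n_sizes = rng.multinomial(n, scenario.size_mixture)
        for size, n_size in zip(SIZE_LEVELS, n_sizes):
            i_size = SIZE_LEVELS.index(size)
            eta = (eff.intercept + eff.size[i_size]
                   + (eff.depth17 if depth == 17.0 else 0.0)
                   + (eff.ahs_slope + eff.size_ahs[i_size]) * ahs_c
                   + site_b[site])
            p = 1.0 / (1.0 + np.exp(-eta))
            severe_draws = rng.random(n_size) < p
            for j in range(n_size):
                healthy, bleached, dead = _severity_composition(severe_draws[j], rng)
                colony_id += 1
                rows.append({
                    "colony_id": f"C{colony_id:06d}",
                    "genus": genus, "site": site, "depth_m": depth,
                    "transect": 1 + (colony_id % 2),
                    "size_class": size,
                    "pct_healthy": healthy, "pct_bleached": bleached,
                    "pct_dead": dead,
                })
    df = pd.DataFrame(rows)
    logger.info("generated %d synthetic colonies across %d cells", len(df), len(cells))
    return df


def pocillopora_like(total: int = 3227, site_sd: float = 0.3,
                     seed: int = 0) -> BleachingScenario:
    """Low baseline severity with a strong large-colony x heat-stress slope.

    Emulates the qualitative pattern of the more heat-tolerant genus: no
    real depth effect, modest overall severity, large colonies markedly more
    sensitive to accumulated heat stress than small or mid colonies.
    """
    cells = [(s, d) for s, d, *_ in _TABLE1_ROWS]
    counts = {(s, d, "Pocillopora"): n
              for (s, d), n in allocate_counts(total, cells).items()}
    effects = GenusEffects(intercept=-2.0, size=(0.0, 0.1, 1.6),
                           depth17=-0.3, ahs_slope=0.5,
                           size_ahs=(0.0, 0.1, 1.5))
    return BleachingScenario(genus_effects={"Pocillopora": effects},
                             counts=counts, site_sd=site_sd, seed=seed)


def acropora_like(total: int = 1874, site_sd: float = 0.3,
                  seed: int = 1) -> BleachingScenario:
    """High baseline severity with a shallow-water excess and size effect.

    Emulates the thermally sensitive genus: most colonies severe, markedly
    more so at 10 m than 17 m, small colonies less affected, essentially no
    heat-stress slope (severe bleaching even at the lowest observed AHS).
    """
    cells = [(s, d) for s, d, *_ in _TABLE1_ROWS]
    counts = {(s, d, "Acropora"): n
              for (s, d), n in allocate_counts(total, cells).items()}
    effects = GenusEffects(intercept=1.0, size=(0.0, 0.7, 0.9),
                           depth17=-1.6, ahs_slope=0.1,
                           size_ahs=(0.0, 0.0, 0.0))
    return BleachingScenario(genus_effects={"Acropora": effects},
                             counts=counts, site_sd=site_sd, seed=seed)


def study_like_survey_scenario(seed: int = 0) -> BleachingScenario:
    """Both genera at the study's colony totals (3227 + 1874 = 5101)."""
    poc = pocillopora_like(seed=seed)
    acr = acropora_like(seed=seed)
    counts = dict(poc.counts)
    counts.update(acr.counts)
    return BleachingScenario(
        genus_effects={**poc.genus_effects, **acr.genus_effects},
        counts=counts, site_sd=poc.site_sd, seed=seed)


def null_bleaching_scenario(total: int = 2400, seed: int = 0) -> BleachingScenario:
    """Intercept-only null: every colony severe with probability one half."""
    cells = [(s, d) for s, d, *_ in _TABLE1_ROWS]
    counts = {(s, d, "Pocillopora"): n
              for (s, d), n in allocate_counts(total, cells).items()}
    return BleachingScenario(
        genus_effects={"Pocillopora": GenusEffects(intercept=0.0)},
        counts=counts, site_sd=0.0, seed=seed)


# ---------------------------------------------------------------------------
# Cell-level severity generator (percent scale, LMM-conformal)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeverityScenario:
    """Gaussian percent-scale generating model matching the LMM.

    pct_severe per site x depth x size cell = Intercept + depth17 +
    ahs_slope * centered AHS + size effects + size:AHS interaction + site
    intercept (SD ``site_sd``) + residual (SD ``resid_sd``).  Used for LMM
    parameter-recovery and test-calibration studies where exact truth on
    the percent scale is needed.
    """

    intercept: float = 20.0
    depth17: float = -8.0
    ahs_slope: float = 6.0
    size_mid: float = 5.0
    size_large: float = 25.0
    inter_mid: float = 1.0
    inter_large: float = 10.0
    site_sd: float = 5.0
    resid_sd: float = 6.0
    genus: str = "Pocillopora"
    cells: tuple = tuple((s, d, a) for s, d, a, _ in _TABLE1_ROWS)

    def true_beta(self) -> np.ndarray:
        """Generating coefficients in the fitted design's column order."""
        return np.array([self.intercept, self.depth17, self.ahs_slope,
                         self.size_mid, self.size_large,
                         self.inter_mid, self.inter_large])


def default_severity_scenario() -> SeverityScenario:
    return SeverityScenario()


def null_interaction_severity_scenario() -> SeverityScenario:
    """Same as the default but with no size x AHS interaction (for type-I error)."""
    return SeverityScenario(inter_mid=0.0, inter_large=0.0)


def generate_severity_table(scenario: SeverityScenario, seed: int = 0) -> pd.DataFrame:
    """One percent-severe row per site x depth x size class.

    AHS is centered on the mean over the scenario's cells, which equals the
    row mean of the generated 24-row table because every cell carries all
    three size classes.
    """
    rng = np.random.default_rng(seed)
    ahs_vals = np.array([a for _, _, a in scenario.cells])
    center = float(ahs_vals.mean())
    sites = sorted({s for s, _, _ in scenario.cells})
    site_b = dict(zip(sites, rng.normal(0.0, scenario.site_sd, len(sites))))
    rows = []
    for site, depth, ahs in scenario.cells:
        ahs_c = ahs - center
        for size in SIZE_LEVELS:
            mid = 1.0 if size == "mid" else 0.0
            large = 1.0 if size == "large" else 0.0
            mean = (scenario.intercept
                    + scenario.depth17 * (1.0 if depth == 17.0 else 0.0)
                    + scenario.ahs_slope * ahs_c
                    + scenario.size_mid * mid + scenario.size_large * large
                    + (scenario.inter_mid * mid + scenario.inter_large * large) * ahs_c
                    + site_b[site])
            rows.append({
                "site": site, "depth_m": depth, "genus": scenario.genus,
                "size_class": size,
                "pct_severe": mean + rng.normal(0.0, scenario.resid_sd),
                "max_ahs_c_weeks": ahs,
            })
    return pd.DataFrame(rows)
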