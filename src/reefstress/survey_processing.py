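"""Colony-level bleaching-survey validation and aggregation.

Belt-transect surveys record, for every colony, the percent of its surface
that is healthy, bleached, or recently dead (turf-colonised but not yet
macroalgae).  A colony is *severely bleached* when bleached + recently dead
is at least 75% of its surface.  Colonies carry a maximum-diameter size
class: small (5-9 cm), mid (10-29 cm), large (>= 30 cm).

The aggregator turns colony records into the site x depth x genus x
size-class severity table consumed by the mixed models, joining each cell to
its maximum accumulated heat stress and attaching a standard error on the
severe percentage (binomial by default, transect-replicate optionally).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("reefstress.survey")

GENERA = ("Pocillopora", "Acropora")
SIZE_LEVELS = ("small", "mid", "large")
DEPTHS_M = (10.0, 17.0)

#: Severe-bleaching threshold: >= 75% bleached and/or recently dead.
SEVERE_THRESHOLD_PCT = 75.0

#: Tolerance on pct_healthy + pct_bleached + pct_dead == 100.
PERCENT_SUM_TOL = 0.5

#: Size-bin edges on continuous diameters: [5,10) [10,30) [30,inf).
SIZE_BIN_EDGES_CM = (5.0, 10.0, 30.0)


# ---------------------------------------------------------------------------
# Colony-level rules
# ---------------------------------------------------------------------------

def classify_severe(pct_bleached, pct_dead,
                    threshold: float = SEVERE_THRESHOLD_PCT):
    """True when bleached + recently-dead cover reaches the severe threshold.

    The threshold is inclusive (a colony exactly 75% bleached is severe) and
    the two conditions are pooled, so a colony 50% bleached and 30% dead is
    severe.  Accepts scalars or arrays.
    """
    total = np.asarray(pct_bleached, dtype=float) + np.asarray(pct_dead, dtype=float)
    out = total >= threshold
    return bool(out) if np.isscalar(pct_bleached) else out


def assign_size_class(diameter_cm: float) -> str:
    """Map a colony maximum diameter to its size class.

    Divers estimate diameters visually to the nearest whole centimetre, so
    a continuous diameter is first rounded half-up to a whole cm and then
    binned half-open: [5,10) -> small, [10,30) -> mid, [30,inf) -> large
    (hence 9.5 cm reads as 10 cm and falls in mid).  Rounded diameters
    below the 5 cm survey minimum are out of survey scope.
    """
    d = float(diameter_cm)
    if not d > 0:
        raise ValueError("diameter must be positive")
    d = np.floor(d + 0.5)  # round half up to the surveyed whole-cm scale
    lo, mid, hi = SIZE_BIN_EDGES_CM
    if d < lo:
        raise ValueError("below survey minimum")
    if d < mid:
        return "small"
    if d < hi:
        return "mid"
    return "large"


def percent_sum_violations(df: pd.DataFrame, tol: float = PERCENT_SUM_TOL) -> pd.Series:
    """Boolean mask of rows whose condition percentages do not sum to 100."""
    total = df["pct_healthy"] + df["pct_bleached"] + df["pct_dead"]
    in_range = True
    for c in ("pct_healthy", "pct_bleached", "pct_dead"):
        in_range = in_range & df[c].between(0, 100)
    return (total - 100.0).abs().gt(tol) | ~in_range


# ---------------------------------------------------------------------------
# Table-level validation
# ---------------------------------------------------------------------------

@dataclass
class SurveyValidationReport:
    """Report-only validation of a colony survey table."""

    n_records: int
    genus_counts: dict[str, int]
    bad_percent_rows: list[int] = field(default_factory=list)
    unknown_genus_rows: list[int] = field(default_factory=list)
    unknown_depth_rows: list[int] = field(default_factory=list)
    below_minimum_rows: list[int] = field(default_factory=list)
    duplicate_colony_ids: list = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return (len(self.bad_percent_rows) + len(self.unknown_genus_rows)
                + len(self.unknown_depth_rows) + len(self.duplicate_colony_ids))

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def validate_survey(records: pd.DataFrame) -> SurveyValidationReport:
    """Validate a colony table without mutating or dropping anything.

    Reports rows violating the percent-sum invariant, unknown genus or depth
    labels, sub-minimum diameters, and duplicate colony ids (when a
    ``colony_id`` column is present), plus per-genus counts so a dataset
    claiming to be a given survey can be checked against its published
    totals.
    """
    df = records.reset_index(drop=True)
    bad_pct = list(df.index[percent_sum_violations(df)])
    unknown_genus = list(df.index[~df["genus"].isin(GENERA)])
    unknown_depth = list(df.index[~df["depth_m"].astype(float).isin(DEPTHS_M)])
    below_min: list[int] = []
    if "diameter_cm" in df.columns:
        diam = pd.to_numeric(df["diameter_cm"], errors="coerce")
        rounded = np.floor(diam + 0.5)
        below_min = list(df.index[diam.notna() & (rounded < SIZE_BIN_EDGES_CM[0])])
    dupes: list = []
    if "colony_id" in df.columns:
        counts = df["colony_id"].value_counts()
        dupes = list(counts.index[counts > 1])
    genus_counts = df["genus"].value_counts().to_dict()
    report = SurveyValidationReport(
        n_records=len(df), genus_counts=genus_counts,
        bad_percent_rows=bad_pct, unknown_genus_rows=unknown_genus,
        unknown_depth_rows=unknown_depth, below_minimum_rows=below_min,
        duplicate_colony_ids=dupes,
    )
    logger.info("survey validation: %d records, %d violation(s)",
                report.n_records, report.n_violations)
    return report


def read_survey_csv(path) -> pd.DataFrame:
    """Read a colony survey CSV, deriving size classes from diameters.

    Requires genus, site, depth_m, transect, pct_healthy, pct_bleached,
    pct_dead and at least one of size_class / diameter_cm.  Records with a
    diameter below the 5 cm survey minimum are excluded with a warning.
    """
    df = pd.read_csv(path)
    required = {"genus", "site", "depth_m", "transect",
                "pct_healthy", "pct_bleached", "pct_dead"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    if "size_class" not in df.columns and "diameter_cm" not in df.columns:
        raise ValueError("survey CSV needs size_class or diameter_cm")
    df["depth_m"] = df["depth_m"].astype(float)
    if "size_class" not in df.columns or df["size_class"].isna().any():
        diam = pd.to_numeric(df["diameter_cm"], errors="coerce")
        too_small = np.floor(diam + 0.5) < SIZE_BIN_EDGES_CM[0]
        if too_small.any():
            logger.warning("excluding %d record(s) below the 5 cm survey minimum",
                           int(too_small.sum()))
            df = df.loc[~too_small].copy()
            diam = diam.loc[~too_small]
        derived = diam.map(lambda d: assign_size_class(d) if np.isfinite(d) else np.nan)
        if "size_class" in df.columns:
            df["size_class"] = df["size_class"].fillna(derived)
        else:
            df["size_class"] = derived
    return df


# ---------------------------------------------------------------------------
# Aggregation to the severity table
# ---------------------------------------------------------------------------

@dataclass
class SeverityTable:
    """Site x depth x genus x size-class severe-bleaching fractions.

    ``table`` columns: site, depth_m, genus, size_class, n, n_severe,
    pct_severe, se_pct, max_ahs_c_weeks, empty_cell.  ``excluded`` lists
    (site, depth, reason) cells dropped because no heat-stress value exists
    for them (e.g. the logger failed continuity QC).
    """

    table: pd.DataFrame
    se_method: str
    excluded: list[tuple[str, float, str]] = field(default_factory=list)


def _binomial_se_pct(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * np.sqrt(p * (1.0 - p) / n)


def aggregate_severity(records: pd.DataFrame,
                       ahs_lookup: Mapping[tuple[str, float], float],
                       se_method: str = "binomial",
                       severe_threshold: float = SEVERE_THRESHOLD_PCT,
                       ) -> SeverityTable:
    """Aggregate colonies to per-cell severe-bleaching percentages.

    Cells whose site x depth has no entry in ``ahs_lookup`` are excluded
    from the model table (and listed in ``excluded``), mirroring the removal
    of sites without continuous temperature data.  Within every retained
    site x depth x genus, all three size classes appear; empty cells are
    flagged ``empty_cell`` rather than dropped.

    ``se_method="binomial"`` gives 100*sqrt(p(1-p)/n) on the cell's
    colonies; ``"transect"`` gives SD of transect-level proportions over
    sqrt(n_transects).
    """
    if records.empty:
        raise ValueError("no survey records")
    if se_method not in ("binomial", "transect"):
        raise ValueError(f"unknown se_method {se_method!r}")
    bad = percent_sum_violations(records)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} record(s) violate the percent-sum invariant; "
            "run validate_survey for details")
    df = records.copy()
    df["depth_m"] = df["depth_m"].astype(float)
    df["severe"] = classify_severe(df["pct_bleached"].to_numpy(),
                                   df["pct_dead"].to_numpy(),
                                   threshold=severe_threshold)

    covered = df.apply(lambda r: (r["site"], r["depth_m"]) in ahs_lookup, axis=1)
    excluded_cells = sorted({(r["site"], r["depth_m"])
                             for _, r in df.loc[~covered].iterrows()})
    excluded = [(s, d, "no heat-stress value (failed temperature QC?)")
                for s, d in excluded_cells]
    for s, d, reason in excluded:
        logger.info("dropping survey cell %s %gm from model table: %s", s, d, reason)
    df = df.loc[covered]
    if df.empty:
        raise ValueError("no survey cell has a heat-stress value")

    rows = []
    for (site, depth, genus), cell in df.groupby(["site", "depth_m", "genus"], sort=True):
        for size in SIZE_LEVELS:
            grp = cell.loc[cell["size_class"] == size]
            n = len(grp)
            n_severe = int(grp["severe"].sum())
            if n > 0:
                p = n_severe / n
                pct = 100.0 * p
                if se_method == "binomial":
                    se = float(_binomial_se_pct(np.array(p), np.array(n)))
                else:
                    props = grp.groupby("transect")["severe"].mean()
                    se = float(100.0 * props.std(ddof=1) / np.sqrt(len(props))) \
                        if len(props) > 1 else np.nan
            else:
                pct, se = np.nan, np.nan
            rows.append({
                "site": site, "depth_m": depth, "genus": genus,
                "size_class": size, "n": n, "n_severe": n_severe,
                "pct_severe": pct, "se_pct": se,
                "max_ahs_c_weeks": float(ahs_lookup[(site, depth)]),
                "empty_cell": n == 0,
            })
    table = pd.DataFrame(rows)
    return SeverityTable(table=table, se_method=se_method, excluded=excluded)
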