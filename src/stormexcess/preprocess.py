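"""Build the county-month modelling panel.

Annual population counts are anchored to June and linearly interpolated to
months; temperature anomalies are deviations of each county-month from that
county's long-run mean for the same calendar month; the panel must form a
complete rectangular county x month grid before any model sees it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PANEL_COLUMNS = [
    "county_id",
    "year",
    "month",
    "deaths",
    "population",
    "temperature",
    "anomaly",
    "time_index",
]

JUNE = 6


def month_range(start: tuple[int, int], end: tuple[int, int]) -> pd.DataFrame:
    """All (year, month) pairs from start through end inclusive."""
    s = start[0] * 12 + start[1] - 1
    e = end[0] * 12 + end[1] - 1
    if e < s:
        raise ValueError("end month precedes start month")
    idx = np.arange(s, e + 1)
    return pd.DataFrame({"year": idx // 12, "month": idx % 12 + 1})


def interpolate_population(
    annual: pd.DataFrame,
    start: tuple[int, int] | None = None,
    end: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Interpolate annual county populations to monthly values.

    Each yearly count is assigned to June of its year; months between
    adjacent Junes lie on the connecting line, and months before the first
    June / after the last June extend the nearest segment's slope, floored
    at one person.

    Returns a DataFrame (county_id, year, month, population).
    """
    req = {"county_id", "year", "population"}
    if not req.issubset(annual.columns):
        raise ValueError(f"annual population needs columns {sorted(req)}")
    if (annual["population"] <= 0).any():
        raise ValueError("population must be positive")
    out = []
    for county, grp in annual.groupby("county_id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if len(years) < 2:
            raise ValueError(f"county {county}: need at least 2 annual counts")
        if np.any(np.diff(years) != 1):
            raise ValueError(f"county {county}: annual series has missing years")
        pop = grp["population"].to_numpy(dtype=float)
        lo = start or (int(years[0]), 1)
        hi = end or (int(years[-1]), 12)
        grid = month_range(lo, hi)
        t = (grid["year"].to_numpy() - years[0]) * 12 + grid["month"].to_numpy() - 1
        anchors = (years - years[0]) * 12 + (JUNE - 1)
        vals = np.interp(t, anchors, pop)
        first_slope = (pop[1] - pop[0]) / 12.0
        last_slope = (pop[-1] - pop[-2]) / 12.0
        before = t < anchors[0]
        after = t > anchors[-1]
        vals[before] = pop[0] + first_slope * (t[before] - anchors[0])
        vals[after] = pop[-1] + last_slope * (t[after] - anchors[-1])
        vals = np.maximum(vals, 1.0)
        out.append(
            pd.DataFrame(
                {
                    "county_id": county,
                    "year": grid["year"],
                    "month": grid["month"],
                    "population": vals,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def compute_anomaly(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill the temperature anomaly column.

    anomaly(county, year, month) = temperature - mean over all years of the
    same county and calendar month; by construction anomalies average to
    zero within every (county, calendar month). Idempotent.
    """
    if panel["temperature"].isna().any():
        raise ValueError("temperature missing for some county-months")
    panel = panel.copy()
    clim = panel.groupby(["county_id", "month"])["temperature"].transform("mean")
    panel["anomaly"] = panel["temperature"] - clim
    return panel


def death_rate(panel: pd.DataFrame) -> pd.Series:
    """Deaths per person-month (descriptive only; models use a log offset)."""
    if (panel["population"] <= 0).any():
        raise ValueError("population must be positive")
    return panel["deaths"] / panel["population"]


def check_grid(panel: pd.DataFrame) -> None:
    """Reject panels that are not a complete rectangular county-month grid."""
    span = panel["year"] * 12 + panel["month"] - 1
    lo, hi = int(span.min()), int(span.max())
    n_months = hi - lo + 1
    counts = panel.groupby("county_id").size()
    bad = counts[counts != n_months]
    if len(bad):
        raise ValueError(
            f"panel is not rectangular: counties {list(bad.index[:5])} do not "
            f"cover all {n_months} months"
        )
    if panel.duplicated(["county_id", "year", "month"]).any():
        raise ValueError("panel has duplicate county-months")


def build_panel(
    deaths: pd.DataFrame,
    annual_population: pd.DataFrame,
    temperature: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the modelling panel from the three input tables.

    deaths: (county_id, year, month, deaths); annual_population:
    (county_id, year, population); temperature: (county_id, year, month,
    temp_c). Returns the full panel with interpolated population, anomaly
    and a 0-based time index.
    """
    if (deaths["deaths"] < 0).any():
        raise ValueError("death counts must be nonnegative")
    span_lo = (int(deaths["year"].min()), 1)
    span_hi = (int(deaths["year"].max()), 12)
    pop = interpolate_population(annual_population, span_lo, span_hi)
    panel = deaths.merge(pop, on=["county_id", "year", "month"], how="left")
    panel = panel.merge(
        temperature.rename(columns={"temp_c": "temperature"}),
        on=["county_id", "year", "month"],
        how="left",
    )
    if panel["population"].isna().any():
        raise ValueError("population missing for some county-months")
    check_grid(panel)
    panel = compute_anomaly(panel)
    t0 = int((panel["year"] * 12 + panel["month"] - 1).min())
    panel["time_index"] = panel["year"] * 12 + panel["month"] - 1 - t0
    panel = panel.sort_values(["county_id", "time_index"]).reset_index(drop=True)
    return panel[PANEL_COLUMNS]
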