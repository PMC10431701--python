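"""Classify county-month tropical-cyclone wind exposure.

Daily county peak sustained winds (knots) are classified on the Beaufort
scale: gale-to-violent-storm force is 34-63 knots, hurricane force is 64
knots and above. A county-month's category is the maximum severity over its
days; the month of exposure and the following calendar month are the target
windows for counterfactual prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NONE = "none"
GALE = "gale_to_violent_storm"
HURRICANE = "hurricane"

#: severity order used when several days or storms fall in one month
SEVERITY = {NONE: 0, GALE: 1, HURRICANE: 2}
CATEGORY_FROM_SEVERITY = {v: k for k, v in SEVERITY.items()}

GALE_THRESHOLD = 34.0
HURRICANE_THRESHOLD = 64.0

WIND_COLUMNS = ["county_id", "date", "storm_name", "wind_knots"]


def classify_wind(wind, gale=GALE_THRESHOLD, hurricane=HURRICANE_THRESHOLD):
    """Classify peak sustained wind (knots) into an exposure category.

    Accepts a scalar or array; winds below 34 knots are unexposed, 34-63.99
    knots gale-to-violent-storm force, >= 64 knots hurricane force.
    """
    w = np.asarray(wind, dtype=float)
    if np.any(w < 0):
        raise ValueError("wind speed must be nonnegative")
    if not gale < hurricane:
        raise ValueError("thresholds must be strictly increasing")
    sev = np.where(w >= hurricane, 2, np.where(w >= gale, 1, 0))
    if np.isscalar(wind) or w.ndim == 0:
        return CATEGORY_FROM_SEVERITY[int(sev)]
    lut = np.array([NONE, GALE, HURRICANE], dtype=object)
    return lut[sev]


def next_month(year: int, month: int) -> tuple[int, int]:
    return (year + 1, 1) if month == 12 else (year, month + 1)


@dataclass
class ExposureCalendar:
    """Classified exposure county-months plus target-month attribution.

    ``calendar`` has one row per county-month that is exposed or is a target
    (month of or month after exposure); months absent from it are unexposed
    non-targets. ``targets`` expands each target county-month into the
    storms it is attributed to: a month shared by several storms is a target
    once and its excess is split equally between them (``weight``), each
    storm row keeping its own wind category.
    """

    calendar: pd.DataFrame
    targets: pd.DataFrame
    thresholds: tuple[float, float] = (GALE_THRESHOLD, HURRICANE_THRESHOLD)

    def exposed(self) -> pd.DataFrame:
        return self.calendar[self.calendar["category"] != NONE]

    def target_months(self) -> pd.DataFrame:
        return self.calendar.loc[
            self.calendar["is_target"], ["county_id", "year", "month"]
        ].reset_index(drop=True)

    def is_target_mask(self, panel: pd.DataFrame) -> np.ndarray:
        """Boolean mask over panel rows that are counterfactual targets."""
        tgt = set(map(tuple, self.target_months().to_numpy()))
        keys = zip(panel["county_id"], panel["year"], panel["month"])
        return np.fromiter((k in tgt for k in keys), dtype=bool, count=len(panel))

    def category_lookup(self) -> dict:
        return {
            (r.county_id, r.year, r.month): r.category
            for r in self.calendar.itertuples()
        }

    def to_csv(self, path) -> None:
        out = self.calendar.copy()
        out.to_csv(path, index=False)


def build_calendar(
    records: pd.DataFrame,
    study_start: tuple[int, int] | None = None,
    study_end: tuple[int, int] | None = None,
    gale: float = GALE_THRESHOLD,
    hurricane: float = HURRICANE_THRESHOLD,
) -> ExposureCalendar:
    """Build the exposure calendar from daily wind records.

    Parameters
    ----------
    records : DataFrame with columns county_id, date (ISO-8601 or datetime),
        storm_name, wind_knots.
    study_start, study_end : optional (year, month) bounds; records outside
        are dropped with a warning, and targets falling past ``study_end``
        are truncated with a warning.
    """
    rec = records.copy()
    missing = [c for c in WIND_COLUMNS if c not in rec.columns]
    if missing:
        raise ValueError(f"wind records missing columns {missing}")
    if rec["wind_knots"].lt(0).any():
        raise ValueError("wind speed must be nonnegative")
    dates = pd.to_datetime(rec["date"])
    rec["year"] = dates.dt.year.astype(int)
    rec["month"] = dates.dt.month.astype(int)

    def _ym(t):
        return t[0] * 12 + (t[1] - 1)

    if study_start is not None or study_end is not None:
        ym = rec["year"] * 12 + (rec["month"] - 1)
        keep = np.ones(len(rec), dtype=bool)
        if study_start is not None:
            keep &= ym >= _ym(study_start)
        if study_end is not None:
            keep &= ym <= _ym(study_end)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} wind records outside the study window",
                stacklevel=2,
            )
            rec = rec[keep]

    rec["severity"] = [
        SEVERITY[c] for c in classify_wind(rec["wind_knots"].to_numpy(), gale, hurricane)
    ]
    exposed = rec[rec["severity"] > 0]

    # per (county, month, storm): the storm's own category that month
    storm_months = (
        exposed.groupby(["county_id", "year", "month", "storm_name"], as_index=False)[
            "severity"
        ].max()
    )

    truncated = 0
    # month-level category and contributing storms
    month_rows: dict[tuple, dict] = {}
    for r in storm_months.itertuples():
        key = (r.county_id, r.year, r.month)
        d = month_rows.setdefault(
            key, {"severity": 0, "storms": [], "is_target": True}
        )
        d["severity"] = max(d["severity"], r.severity)
        d["storms"].append(r.storm_name)

    # attribution rows: month-of for the exposure month, month-after next
    attribution: list[dict] = []
    for r in storm_months.itertuples():
        attribution.append(
            dict(
                county_id=r.county_id,
                year=r.year,
                month=r.month,
                storm_name=r.storm_name,
                category=CATEGORY_FROM_SEVERITY[r.severity],
                phase="month_of",
            )
        )
        ny, nm = next_month(r.year, r.month)
        if study_end is not None and _ym((ny, nm)) > _ym(study_end):
            truncated += 1
            continue
        attribution.append(
            dict(
                county_id=r.county_id,
                year=ny,
                month=nm,
                storm_name=r.storm_name,
                category=CATEGORY_FROM_SEVERITY[r.severity],
                phase="month_after",
            )
        )
        after = month_rows.setdefault(
            (r.county_id, ny, nm), {"severity": 0, "storms": [], "is_target": True}
        )

    if truncated:
        warnings.warn(
            f"{truncated} month-after target(s) fall past the study window and were truncated",
            stacklevel=2,
        )

    targets = pd.DataFrame(
        attribution,
        columns=["county_id", "year", "month", "storm_name", "category", "phase"],
    )
    if len(targets):
        # a storm exposing a county in consecutive months claims the shared
        # month once, as month-of (its own exposure there takes precedence)
        targets = (
            targets.sort_values("phase", key=lambda s: s.ne("month_of"))
            .drop_duplicates(["county_id", "year", "month", "storm_name"])
            .reset_index(drop=True)
        )
        nshare = targets.groupby(["county_id", "year", "month"])["storm_name"].transform(
            "count"
        )
        targets["weight"] = 1.0 / nshare
        targets = targets.sort_values(
            ["county_id", "year", "month", "storm_name"]
        ).reset_index(drop=True)
    else:
        targets["weight"] = pd.Series(dtype=float)

    cal_records = [
        dict(
            county_id=k[0],
            year=k[1],
            month=k[2],
            category=CATEGORY_FROM_SEVERITY[v["severity"]],
            storms=";".join(sorted(set(v["storms"]))),
            is_target=True,
        )
        for k, v in month_rows.items()
    ]
    calendar = pd.DataFrame(
        cal_records,
        columns=["county_id", "year", "month", "category", "storms", "is_target"],
    )
    calendar = calendar.sort_values(["county_id", "year", "month"]).reset_index(
        drop=True
    )
    return ExposureCalendar(calendar=calendar, targets=targets, thresholds=(gale, hurricane))


def tally_county_months(calendar: ExposureCalendar) -> pd.DataFrame:
    """Annual counts of tropical-cyclone / gale-to-violent-storm / hurricane
    county-months; the tropical-cyclone column is the sum of the other two.
    """
    exp = calendar.exposed()
    if len(exp) == 0:
        return pd.DataFrame(
            columns=["year", "tropical_cyclone", "gale_to_violent_storm", "hurricane"]
        ).astype(int)
    counts = (
        exp.groupby(["year", "category"]).size().unstack(fill_value=0).reset_index()
    )
    for cat in (GALE, HURRICANE):
        if cat not in counts:
            counts[cat] = 0
    counts["tropical_cyclone"] = counts[GALE] + counts[HURRICANE]
    out = counts[["year", "tropical_cyclone", GALE, HURRICANE]].rename(
        columns={GALE: "gale_to_violent_storm", HURRICANE: "hurricane"}
    )
    return out.sort_values("year").reset_index(drop=True)
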