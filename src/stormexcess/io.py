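"""CSV schemas and schema-checked readers/writers for the pipeline files.

All month fields are explicit (year, month) integer columns with month in
1..12; counts are serialized as integers, rates and draws as decimal text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import ExposureCalendar

SCHEMAS = {
    "deaths": ["county_id", "year", "month", "deaths"],
    "population": ["county_id", "year", "population"],
    "temperature": ["county_id", "year", "month", "temp_c"],
    "wind": ["county_id", "date", "storm_name", "wind_knots"],
    "svi": [
        "county_id",
        "overall_pct",
        "ses_pct",
        "household_pct",
        "minority_pct",
        "housing_transport_pct",
    ],
    "state_map": ["county_id", "state", "region"],
    "calendar": ["county_id", "year", "month", "category", "storms", "is_target"],
    "targets": ["county_id", "year", "month", "storm_name", "category", "phase", "weight"],
    "truth": ["county_id", "year", "month", "latent_log_mean", "injected_excess", "category"],
}

_INT_COLS = {"year", "month", "deaths", "population"}


def _check(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    cols = SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} for schema '{kind}'")
    if "month" in cols and len(df) and not df["month"].between(1, 12).all():
        bad = df.index[~df["month"].between(1, 12)][:5].tolist()
        raise ValueError(f"{path}: month outside 1..12 at rows {bad}")
    return df[cols]


def read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _check(df, kind, path)


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    out = _check(df.copy(), kind, path)
    for c in out.columns:
        if c in _INT_COLS:
            out[c] = out[c].astype(int)
        elif out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.6g}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_calendar(cal_path, targets_path) -> ExposureCalendar:
    cal = read_table(cal_path, "calendar")
    cal["storms"] = cal["storms"].fillna("")
    tgt = read_table(targets_path, "targets")
    return ExposureCalendar(calendar=cal, targets=tgt)


def write_calendar(calendar: ExposureCalendar, cal_path, targets_path) -> None:
    write_table(calendar.calendar, cal_path, "calendar")
    write_table(calendar.targets, targets_path, "targets")


def save_draws(path, index: pd.DataFrame, draws: np.ndarray) -> None:
    """Pooled draw matrix with its (county, year, month) index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        draws=draws,
        county_id=index["county_id"].to_numpy(dtype="U16"),
        year=index["year"].to_numpy(dtype=np.int64),
        month=index["month"].to_numpy(dtype=np.int64),
    )


def load_draws(path) -> tuple[pd.DataFrame, np.ndarray]:
    with np.load(path, allow_pickle=False) as z:
        index = pd.DataFrame(
            {
                "county_id": z["county_id"],
                "year": z["year"],
                "month": z["month"],
            }
        )
        return index, z["draws"]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, stage: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
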