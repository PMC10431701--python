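"""Out-of-sample validation and inverse-error ensemble weighting.

Cyclone-free two-month windows are withheld, every ensemble member is refit
without them and predicts the withheld totals pooled over counties, and the
signed percentage error per window is averaged into a mean percentage error
(MPE) per model. Ensemble draw counts are then allocated proportionally to
1/|MPE| with the best model anchored at the 1000-draw cap and a floor of 0
for non-convergent members.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .countmodel import FitConfig, ModelSpec, model_from_panel
from .exposure import NONE, ExposureCalendar

MAX_DRAWS = 1000


def default_windows(
    panel: pd.DataFrame, calendar: ExposureCalendar, months: tuple[int, int] = (3, 4)
) -> list[list[tuple[int, int]]]:
    """First and last year whose chosen months are cyclone-free in every
    county, each returned as a 2-month window."""
    exposed = calendar.exposed()
    bad_years = set(exposed.loc[exposed["month"].isin(months), "year"])
    target = calendar.calendar
    bad_years |= set(target.loc[target["month"].isin(months), "year"])
    years = sorted(set(panel["year"]))
    clean = [y for y in years if y not in bad_years]
    if len(clean) < 2:
        raise ValueError("fewer than two cyclone-free validation years available")
    return [
        [(clean[0], months[0]), (clean[0], months[1])],
        [(clean[-1], months[0]), (clean[-1], months[1])],
    ]


def _window_mask(sub: pd.DataFrame, window: list[tuple[int, int]]) -> np.ndarray:
    keys = set(window)
    return np.fromiter(
        ((y, m) in keys for y, m in zip(sub["year"], sub["month"])),
        dtype=bool,
        count=len(sub),
    )


class ValidationResult:
    """Per-model, per-window predictions and percentage errors."""

    def __init__(self, table: pd.DataFrame, converged: dict[int, bool]):
        self.table = table
        self.converged = converged

    def mean_percentage_error(self) -> pd.Series:
        return self.table.groupby("model_id")["pct_error"].mean()

    def window_percentage_error(self, window_id: int) -> pd.Series:
        """Per-model error from a single window (window-sensitivity runs)."""
        sub = self.table[self.table["window_id"] == window_id]
        if len(sub) == 0:
            raise ValueError(f"no window with id {window_id}")
        return sub.set_index("model_id")["pct_error"]

    def ensemble_percentage_error(self, weights: dict[int, int]) -> float:
        """MPE of the weight-pooled ensemble prediction over the windows."""
        t = self.table.copy()
        t["w"] = t["model_id"].map(weights).fillna(0)
        per_window = t.groupby("window_id").apply(
            lambda g: 100.0
            * ((g["predicted"] * g["w"]).sum() / g["w"].sum() - g["observed"].iloc[0])
            / g["observed"].iloc[0],
            include_groups=False,
        )
        return float(per_window.mean())

    def to_frame(self, weights: dict[int, int] | None = None) -> pd.DataFrame:
        out = self.table.copy()
        mpe = self.mean_percentage_error()
        out["mean_pct_error"] = out["model_id"].map(mpe)
        if weights is not None:
            out["draws_allocated"] = out["model_id"].map(weights)
        return out


def run_validation(
    panel: pd.DataFrame,
    calendar: ExposureCalendar,
    windows: list[list[tuple[int, int]]],
    specs: list[ModelSpec],
    config: FitConfig | None = None,
    counties: list | None = None,
    warm_hyper: dict | None = None,
    n_draws: int = 400,
    seed: int = 0,
) -> ValidationResult:
    """Refit each model with each window withheld and score its pooled
    percentage error.

    counties restricts the pooled set (validation error is a global model
    property; a representative subset is acceptable). warm_hyper maps
    (county_id, model_id) -> hyperparameter dict used as optimiser start.
    """
    config = config or FitConfig()
    if counties is None:
        counties = sorted(panel["county_id"].unique())

    exposed = {
        (r.county_id, r.year, r.month)
        for r in calendar.exposed().itertuples()
    }
    targets = set(map(tuple, calendar.target_months().to_numpy()))
    for w_id, window in enumerate(windows):
        for county in counties:
            for (y, m) in window:
                if (county, y, m) in exposed:
                    raise ValueError(
                        f"validation window {window} overlaps exposed county-month "
                        f"({county}, {y}, {m})"
                    )
                if (county, y, m) in targets:
                    warnings.warn(
                        f"validation window {window} overlaps a target month "
                        f"({county}, {y}, {m})",
                        stacklevel=2,
                    )

    rows = []
    converged: dict[int, bool] = {s.model_id: True for s in specs}
    rng = np.random.default_rng(seed)
    warm = dict(warm_hyper or {})
    for w_id, window in enumerate(windows):
        preds = {s.model_id: 0.0 for s in specs}
        observed = 0.0
        for county in counties:
            sub = panel[panel["county_id"] == county].sort_values("time_index")
            tmask = calendar.is_target_mask(sub)
            wmask = _window_mask(sub, window)
            observed += float(sub.loc[wmask, "deaths"].sum())
            widx = np.where(wmask)[0]
            for spec in specs:
                cfg = config
                if (county, spec.model_id) in warm:
                    cfg = replace(config, init_hyper=warm[(county, spec.model_id)])
                model = model_from_panel(
                    panel, spec, county, target_mask=tmask, extra_holdout=wmask,
                    config=cfg,
                )
                res = model.fit()
                warm[(county, spec.model_id)] = dict(res.hyper)
                if not res.converged:
                    converged[spec.model_id] = False
                draws = res.predict_counterfactual(widx, n_draws, rng)
                preds[spec.model_id] += float(draws.sum(axis=0).mean())
        if observed <= 0:
            raise ValueError(f"observed deaths total zero in window {window}")
        for spec in specs:
            rows.append(
                dict(
                    model_id=spec.model_id,
                    window_id=w_id,
                    window=str(window),
                    predicted=preds[spec.model_id],
                    observed=observed,
                    pct_error=100.0 * (preds[spec.model_id] - observed) / observed,
                )
            )
    return ValidationResult(pd.DataFrame(rows), converged)


def compute_weights(
    mpe: pd.Series | dict,
    converged: dict[int, bool] | None = None,
    max_draws: int = MAX_DRAWS,
) -> dict[int, int]:
    """Allocate posterior draws per model inversely to |MPE|.

    The best (smallest |MPE|) convergent model is anchored at the
    ``max_draws`` cap; a model with MPE exactly 0 takes the cap and others
    scale against the next-best finite value; non-convergent models get 0.
    """
    mpe = pd.Series(mpe, dtype=float)
    ok = mpe.index.to_series().map(
        lambda m: (converged or {}).get(m, True)
    ) & np.isfinite(mpe)
    if not ok.any():
        raise ValueError("no convergent model with finite validation error")
    weights = {int(m): 0 for m in mpe.index}
    amag = mpe[ok].abs()
    nonzero = amag[amag > 0]
    for m, a in amag.items():
        if a == 0:
            weights[int(m)] = max_draws
        elif len(nonzero):
            weights[int(m)] = int(round(max_draws * nonzero.min() / a))
    return weights


def pool_draws(
    draws_by_model: dict[int, np.ndarray],
    weights: dict[int, int],
    seed: int,
) -> np.ndarray:
    """Pool per-model counterfactual draws into the weighted ensemble.

    Each model's (n_targets x n_draws) draw matrix is column-shuffled with a
    model-specific seeded permutation (keeping each joint draw intact across
    target months) and its first ``weight`` columns are concatenated.
    """
    if sum(weights.get(m, 0) for m in draws_by_model) == 0:
        raise ValueError("all ensemble weights are zero")
    parts = []
    for model_id in sorted(draws_by_model):
        w = int(weights.get(model_id, 0))
        if w == 0:
            continue
        draws = draws_by_model[model_id]
        if draws.shape[1] < w:
            raise ValueError(
                f"model {model_id} supplies {draws.shape[1]} draws but its "
                f"weight is {w}; increase the posterior sample size"
            )
        rng = np.random.default_rng([seed, model_id])
        perm = rng.permutation(draws.shape[1])[:w]
        parts.append(draws[:, perm])
    return np.concatenate(parts, axis=1)
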