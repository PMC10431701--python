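"""Ensemble excess-mortality model: the top-level Model/Results pair.

`ExcessDeathEnsemble` ties the stages together in the statsmodels style: it
is built from a county-month panel and an exposure calendar, and `fit()`
runs validation, inverse-error draw allocation, per-county member fits,
counterfactual prediction for the month of and month after each exposure,
and pooling. The returned `ExcessDeathResults` carries the pooled excess
draws and exposes grouped summaries, group comparisons and a text summary.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import aggregation as agg
from .countmodel import FitConfig, ModelSpec, enumerate_specs, model_from_panel
from .exposure import ExposureCalendar
from .validation import (
    compute_weights,
    default_windows,
    pool_draws,
    run_validation,
)


class ExcessDeathEnsemble:
    """Bayesian ensemble model for short-term post-cyclone excess deaths.

    Parameters
    ----------
    panel : complete county-month panel (deaths, population, temperature,
        anomaly, time_index).
    calendar : ExposureCalendar from the wind classifier.
    specs : ensemble members; defaults to the full 16-model grid.
    fit_config : Laplace fit configuration shared by all members.
    state_map, svi : optional county metadata used by grouped summaries.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        calendar: ExposureCalendar,
        specs: list[ModelSpec] | None = None,
        fit_config: FitConfig | None = None,
        state_map: pd.DataFrame | None = None,
        svi: pd.DataFrame | None = None,
    ):
        self.panel = panel.sort_values(["county_id", "time_index"]).reset_index(
            drop=True
        )
        self.calendar = calendar
        self.specs = specs or enumerate_specs()
        self.fit_config = fit_config or FitConfig()
        self.state_map = state_map
        self.svi = svi

    def fit(
        self,
        seed: int = 0,
        windows: list | None = None,
        validation_counties: list | None = None,
        weights: dict[int, int] | None = None,
        progress: bool = False,
    ) -> "ExcessDeathResults":
        """Run validation, member fits, prediction and pooling.

        weights may be supplied directly (e.g. from a previous validation
        run or a sensitivity variant), in which case validation is skipped.
        """
        cfg = self.fit_config
        t0 = time.time()
        target_df = self.calendar.target_months()
        exposed_counties = sorted(set(target_df["county_id"]))
        if not exposed_counties:
            raise ValueError("calendar contains no target county-months")

        # fit members on exposed counties, warm hyperparameters for reuse
        county_results: dict[tuple, object] = {}
        warm: dict[tuple, dict] = {}
        for county in exposed_counties:
            sub = self.panel[self.panel["county_id"] == county].sort_values(
                "time_index"
            )
            tmask = self.calendar.is_target_mask(sub)
            for spec in self.specs:
                model = model_from_panel(
                    self.panel, spec, county, target_mask=tmask, config=cfg
                )
                res = model.fit()
                county_results[(county, spec.model_id)] = res
                warm[(county, spec.model_id)] = dict(res.hyper)
            if progress:
                print(f"fitted {county} ({time.time() - t0:.0f}s)", flush=True)

        valres = None
        if weights is None:
            if windows is None:
                windows = default_windows(self.panel, self.calendar)
            valres = run_validation(
                self.panel,
                self.calendar,
                windows,
                self.specs,
                config=cfg,
                counties=validation_counties,
                warm_hyper=warm,
                seed=seed + 1,
            )
            weights = compute_weights(
                valres.mean_percentage_error(),
                valres.converged,
                max_draws=cfg.n_draws,
            )

        # counterfactual prediction and pooling, county by county
        index_rows = []
        pooled_blocks = []
        observed = []
        rng = np.random.default_rng([seed, 2])
        for county in exposed_counties:
            sub = self.panel[self.panel["county_id"] == county].sort_values(
                "time_index"
            )
            tmask = self.calendar.is_target_mask(sub)
            tidx = np.where(tmask)[0]
            if len(tidx) == 0:
                continue
            draws_by_model = {}
            for spec in self.specs:
                res = county_results[(county, spec.model_id)]
                draws_by_model[spec.model_id] = res.predict_counterfactual(
                    tidx, cfg.n_draws, rng
                )
            pooled = pool_draws(draws_by_model, weights, seed=seed)
            pooled_blocks.append(pooled)
            rows = sub.iloc[tidx]
            observed.append(rows["deaths"].to_numpy(dtype=float))
            index_rows.append(rows[["county_id", "year", "month", "deaths"]])

        index = pd.concat(index_rows, ignore_index=True)
        counterfactual = np.vstack(pooled_blocks)
        obs = np.concatenate(observed)
        excess = agg.ExcessDrawSet(
            index[["county_id", "year", "month"]],
            agg.excess_draws(obs, counterfactual),
        )
        return ExcessDeathResults(
            model=self,
            excess=excess,
            counterfactual=counterfactual,
            observed_index=index,
            weights=weights,
            validation=valres,
            county_results=county_results,
            seed=seed,
            elapsed=time.time() - t0,
        )


def window_sensitivity(results: "ExcessDeathResults", seed: int | None = None) -> pd.DataFrame:
    """Sensitivity of excess estimates to the choice of validation window.

    Re-pools the (already fitted) ensemble with weights derived from each
    single validation window instead of their average and reports the mean
    absolute difference of county-month point estimates from the main run.
    """
    res = results
    if res.validation is None:
        raise ValueError("results were fitted with externally supplied weights")
    ens = res.model
    seed = res.seed if seed is None else seed
    main_points = res.excess.draws.mean(axis=1)
    rows = []
    for w_id in sorted(res.validation.table["window_id"].unique()):
        w_err = res.validation.window_percentage_error(w_id)
        weights = compute_weights(
            w_err, res.validation.converged, max_draws=ens.fit_config.n_draws
        )
        alt = ens.fit(seed=seed, weights=weights)
        diff = np.abs(alt.excess.draws.mean(axis=1) - main_points)
        rows.append(
            dict(
                window_id=int(w_id),
                mean_abs_difference=float(diff.mean()),
                max_abs_difference=float(diff.max()),
            )
        )
    return pd.DataFrame(rows)


def split_period_difference(
    results: "ExcessDeathResults", seed: int | None = None
) -> pd.DataFrame:
    """Consistency of excess estimates under split-period refits.

    The panel is split into its first and second halves of years; the
    ensemble is refit on each half (reusing the main run's validation
    weights) and half-period county-month excess estimates are compared
    with the main run's on the same target months.
    """
    ens = results.model
    seed = results.seed if seed is None else seed
    years = sorted(ens.panel["year"].unique())
    mid = len(years) // 2
    halves = [set(years[:mid]), set(years[mid:])]
    main = results.excess.index.copy()
    main["point"] = results.excess.draws.mean(axis=1)
    rows = []
    for i, keep in enumerate(halves):
        sub_panel = ens.panel[ens.panel["year"].isin(keep)].copy()
        t0 = int((sub_panel["year"] * 12 + sub_panel["month"] - 1).min())
        sub_panel["time_index"] = (
            sub_panel["year"] * 12 + sub_panel["month"] - 1 - t0
        )
        cal = ExposureCalendar(
            calendar=ens.calendar.calendar[
                ens.calendar.calendar["year"].isin(keep)
            ].reset_index(drop=True),
            targets=ens.calendar.targets[
                ens.calendar.targets["year"].isin(keep)
            ].reset_index(drop=True),
        )
        if len(cal.target_months()) == 0:
            continue
        half_ens = ExcessDeathEnsemble(
            sub_panel, cal, specs=ens.specs, fit_config=ens.fit_config
        )
        half_res = half_ens.fit(seed=seed, weights=results.weights)
        half = half_res.excess.index.copy()
        half["point_half"] = half_res.excess.draws.mean(axis=1)
        merged = main.merge(half, on=["county_id", "year", "month"])
        rows.append(
            dict(
                period=("first_half", "second_half")[i],
                n_targets=len(merged),
                mean_abs_difference=float(
                    np.abs(merged["point"] - merged["point_half"]).mean()
                ),
            )
        )
    return pd.DataFrame(rows)


class ExcessDeathResults:
    """Fitted ensemble: pooled excess draws plus diagnostics."""

    def __init__(
        self,
        model,
        excess,
        counterfactual,
        observed_index,
        weights,
        validation,
        county_results,
        seed,
        elapsed,
    ):
        self.model = model
        self.excess = excess
        self.counterfactual = counterfactual
        self.observed_index = observed_index
        self.weights = weights
        self.validation = validation
        self.county_results = county_results
        self.seed = seed
        self.elapsed = elapsed

    # ------------------------------------------------------------------ #
    def total_excess(self) -> agg.ExcessSummary:
        """National total over all target months (no probability filter)."""
        vec = self.excess.shuffled(self.seed).sum(axis=0)
        return agg.summarize(vec, unit=("national",))

    def by(
        self,
        grouping: list[str],
        probability_filter: float | None = None,
        tertile_kwargs: dict | None = None,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Grouped excess summaries; see :func:`stormexcess.aggregate.aggregate`."""
        tertiles = None
        if "tertile" in grouping:
            if self.model.svi is None:
                raise ValueError("ensemble was built without an SVI table")
            tertiles = agg.assign_tertiles(
                self.model.svi,
                state_map=self.model.state_map,
                **(tertile_kwargs or {}),
            )
        return agg.aggregate(
            self.excess,
            grouping,
            targets=self.model.calendar.targets,
            state_map=self.model.state_map,
            tertiles=tertiles,
            probability_filter=probability_filter,
            seed=self.seed if seed is None else seed,
        )

    def compare_tertiles(
        self, t_a: int = 3, t_b: int = 1, tertile_kwargs: dict | None = None
    ) -> dict[str, float]:
        """Posterior probability that tertile A's excess exceeds tertile B's."""
        tertiles = agg.assign_tertiles(
            self.model.svi,
            state_map=self.model.state_map,
            **(tertile_kwargs or {}),
        )
        a = agg.group_draw_vector(
            self.excess, tertiles[tertiles == t_a].index, seed=self.seed
        )
        b = agg.group_draw_vector(
            self.excess, tertiles[tertiles == t_b].index, seed=self.seed
        )
        return agg.compare_groups(a, b, seed=self.seed)

    def validation_table(self) -> pd.DataFrame:
        if self.validation is None:
            return pd.DataFrame(
                {"model_id": list(self.weights), "draws_allocated": list(self.weights.values())}
            )
        return self.validation.to_frame(self.weights)

    def summary(self) -> str:
        tot = self.total_excess()
        n_target = len(self.excess.index)
        lines = [
            "Tropical-cyclone excess mortality ensemble",
            "=" * 48,
            f"members: {len(self.model.specs)}   pooled draws: {self.excess.n_draws}",
            f"target county-months: {n_target}   counties: "
            f"{self.excess.index['county_id'].nunique()}",
            f"total excess deaths: {tot.point_estimate:.1f} "
            f"[95% CrI {tot.cri_low:.1f}, {tot.cri_high:.1f}]  "
            f"P(excess>0) = {tot.posterior_probability:.3f}",
        ]
        if self.validation is not None:
            mpe = self.validation.mean_percentage_error()
            lines.append("model  mean % error  draws")
            for m, e in mpe.items():
                lines.append(f"  {m:>3d}  {e:>+11.3f}  {self.weights.get(m, 0):>5d}")
            lines.append(
                f"ensemble mean % error: "
                f"{self.validation.ensemble_percentage_error(self.weights):+.3f}"
            )
        return "\n".join(lines)
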