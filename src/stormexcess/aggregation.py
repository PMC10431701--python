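"""Excess-death draws, summaries and grouped aggregation.

Excess draws are observed deaths minus pooled counterfactual draws per
target county-month. Aggregation sums member draw vectors draw-wise after a
deterministic per-unit shuffle (county fits are independent, so their
posteriors must be paired independently rather than by shared draw order);
because each county-month's shuffle depends only on its own key and the
seed, county -> state -> national sums are conserved exactly per draw
index. Probability-filtered totals keep only member units whose own
posterior probability of excess exceeds the threshold, following the
">95% posterior probability" convention for headline totals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_DRAWS = 100

GROUP_KEYS = {"county", "state", "national", "year", "storm", "category", "tertile"}

SVI_COMPONENTS = {
    "overall": "overall_pct",
    "socioeconomic": "ses_pct",
    "household": "household_pct",
    "minority": "minority_pct",
    "housing_transport": "housing_transport_pct",
}


@dataclass
class ExcessSummary:
    unit: tuple
    point_estimate: float
    cri_low: float
    cri_high: float
    posterior_probability: float
    n_draws: int
    n_members: int = 1


def excess_draws(observed: np.ndarray, counterfactual: np.ndarray) -> np.ndarray:
    """observed - counterfactual draw, per target month and draw index."""
    observed = np.asarray(observed, dtype=float)
    cf = np.asarray(counterfactual, dtype=float)
    if observed.shape[0] != cf.shape[0]:
        raise ValueError("observed and draws are not aligned")
    if np.any(np.isnan(observed)):
        raise ValueError("missing observed deaths for a target month")
    return observed[:, None] - cf


def summarize(draws: np.ndarray, unit: tuple = ()) -> ExcessSummary:
    """Point estimate (posterior mean), 2.5/97.5 percentile credible
    interval, and posterior probability of excess > 0."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {draws.size}")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return ExcessSummary(
        unit=unit,
        point_estimate=float(draws.mean()),
        cri_low=float(lo),
        cri_high=float(hi),
        posterior_probability=float(np.mean(draws > 0)),
        n_draws=int(draws.size),
    )


def _unit_rng(seed: int, key: tuple) -> np.random.Generator:
    digest = hashlib.sha256(repr(key).encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(seed), sub])


class ExcessDrawSet:
    """Excess draw vectors per target county-month.

    index: DataFrame with columns county_id, year, month (one row per
    target month); draws: (n_rows x n_draws) array aligned with it.
    """

    def __init__(self, index: pd.DataFrame, draws: np.ndarray):
        if len(index) != draws.shape[0]:
            raise ValueError("index and draw matrix are misaligned")
        self.index = index.reset_index(drop=True)
        self.draws = np.asarray(draws, dtype=float)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def shuffled(self, seed: int) -> np.ndarray:
        """Independently permute each row's draws, deterministically in the
        row key; this fixed per-unit ordering is what makes grouped sums
        conserve exactly across aggregation levels."""
        out = np.empty_like(self.draws)
        for i, row in enumerate(self.index.itertuples(index=False)):
            key = (row.county_id, int(row.year), int(row.month))
            perm = _unit_rng(seed, key).permutation(self.draws.shape[1])
            out[i] = self.draws[i, perm]
        return out


def assign_tertiles(
    svi: pd.DataFrame,
    scope: str = "national",
    component: str = "overall",
    mode: str = "rank",
    state_map: pd.DataFrame | None = None,
) -> pd.Series:
    """Tertile labels 1 (least vulnerable) .. 3 (most vulnerable).

    mode="rank" splits counties into near-equal thirds by rank of the
    chosen percentile (ties broken by county id); mode="cutpoint" cuts at
    percentile 1/3 and 2/3 of the national distribution, which can give
    unequal tertile sizes in a subsample. scope="per-state" ranks within
    each state (requires state_map).
    """
    col = SVI_COMPONENTS.get(component, component)
    if col not in svi.columns:
        raise ValueError(f"unknown SVI component {component!r}")
    df = svi[["county_id", col]].copy()
    if scope == "per-state":
        if state_map is None:
            raise ValueError("per-state scope requires a state map")
        df = df.merge(state_map[["county_id", "state"]], on="county_id")
        groups = [g for _, g in df.groupby("state")]
    elif scope == "national":
        groups = [df]
    else:
        raise ValueError("scope must be 'national' or 'per-state'")

    labels = {}
    for g in groups:
        n = len(g)
        if n < 3:
            raise ValueError("need at least 3 counties per scope for tertiles")
        if mode == "cutpoint":
            for r in g.itertuples(index=False):
                pct = getattr(r, col)
                labels[r.county_id] = 1 + (pct > 1.0 / 3.0) + (pct > 2.0 / 3.0)
        elif mode == "rank":
            ordered = g.sort_values([col, "county_id"])
            q, rem = divmod(n, 3)
            sizes = [q + (1 if i < rem else 0) for i in range(3)]
            tert = np.repeat([1, 2, 3], sizes)
            for cid, t in zip(ordered["county_id"], tert):
                labels[cid] = int(t)
        else:
            raise ValueError("mode must be 'rank' or 'cutpoint'")
    return pd.Series(labels, name="tertile").rename_axis("county_id")


def aggregate(
    excess: ExcessDrawSet,
    grouping: list[str],
    *,
    targets: pd.DataFrame | None = None,
    state_map: pd.DataFrame | None = None,
    tertiles: pd.Series | None = None,
    probability_filter: float | None = None,
    member_keys: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped excess-death summaries.

    grouping: subset of {"county", "state", "national", "year", "storm",
    "category", "tertile"}. "storm"/"category" expand target months through
    the exposure attribution table (``targets``: county_id, year, month,
    storm_name, category, weight), splitting shared months by weight.
    probability_filter keeps only member units (default: county-year, plus
    category/storm when grouped on) whose own posterior probability exceeds
    the threshold. Draw pairing across units uses the per-unit seeded
    shuffle of :meth:`ExcessDrawSet.shuffled`.
    """
    unknown = set(grouping) - GROUP_KEYS
    if unknown:
        raise ValueError(f"unknown grouping keys {sorted(unknown)}")
    base = excess.index.copy()
    base["_row"] = np.arange(len(base))
    base["_weight"] = 1.0

    need_attrib = "storm" in grouping or "category" in grouping
    if need_attrib:
        if targets is None:
            raise ValueError("storm/category grouping needs the attribution table")
        base = base.merge(
            targets.rename(columns={"storm_name": "storm"})[
                ["county_id", "year", "month", "storm", "category", "weight"]
            ],
            on=["county_id", "year", "month"],
            how="left",
        )
        if base["weight"].isna().any():
            missing = base.loc[base["weight"].isna(), ["county_id", "year", "month"]]
            raise ValueError(
                f"target months missing from attribution table: {missing.head().values}"
            )
        base["_weight"] = base["weight"]

    if "state" in grouping or ("national" in grouping):
        if "state" in grouping:
            if state_map is None:
                raise ValueError("state grouping needs a county -> state map")
            base = base.merge(
                state_map[["county_id", "state"]], on="county_id", how="left"
            )
            if base["state"].isna().any():
                raise ValueError("counties missing from the state map")
        else:
            base["national"] = "national"
    if "national" in grouping:
        base["national"] = "national"
    if "tertile" in grouping:
        if tertiles is None:
            raise ValueError("tertile grouping needs tertile labels")
        base = base.merge(
            tertiles.rename("tertile").reset_index(), on="county_id", how="left"
        )
        if base["tertile"].isna().any():
            raise ValueError("counties missing tertile labels")

    group_cols = [g for g in grouping if g != "national"] or []
    if "national" in grouping:
        group_cols = ["national"] + group_cols
    rename = {"county": "county_id"}
    group_cols = [rename.get(g, g) for g in group_cols]

    if member_keys is None:
        member_cols = ["county_id", "year"]
        for extra in ("category", "storm"):
            if extra in grouping:
                member_cols.append(extra)
    else:
        member_cols = [rename.get(g, g) for g in member_keys]

    shuffled = excess.shuffled(seed)
    weighted = shuffled[base["_row"].to_numpy()] * base["_weight"].to_numpy()[:, None]

    # member-level vectors (for the probability filter)
    members = base.groupby(member_cols, dropna=False, sort=True).indices
    member_vec = {k: weighted[idx].sum(axis=0) for k, idx in members.items()}
    member_prob = {k: float(np.mean(v > 0)) for k, v in member_vec.items()}

    passing = {
        k
        for k, p in member_prob.items()
        if probability_filter is None or p > probability_filter
    }

    # map members to groups
    cols = list(dict.fromkeys(member_cols + group_cols))
    mem_frame = base[cols].drop_duplicates(member_cols)
    rows = []
    for gkey, gsub in mem_frame.groupby(group_cols, dropna=False, sort=True):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        mkeys = [
            tuple(r) if len(member_cols) > 1 else r[0]
            for r in gsub[member_cols].itertuples(index=False)
        ]
        contributing = [k for k in mkeys if k in passing]
        if not contributing:
            vec = np.zeros(excess.n_draws)
        else:
            vec = np.sum([member_vec[k] for k in contributing], axis=0)
        s = summarize(vec, unit=gkey)
        rows.append(
            {
                **dict(zip(group_cols, gkey)),
                "point_estimate": s.point_estimate,
                "cri_low": s.cri_low,
                "cri_high": s.cri_high,
                "posterior_probability": s.posterior_probability,
                "n_draws": s.n_draws,
                "n_members": len(contributing),
                "n_candidate_members": len(mkeys),
                "filter": probability_filter,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def group_draw_vector(
    excess: ExcessDrawSet,
    county_ids,
    seed: int = 0,
    years=None,
) -> np.ndarray:
    """Draw-wise sum of the shuffled vectors of the selected counties
    (optionally restricted to years); used for group-vs-group comparisons."""
    base = excess.index
    mask = base["county_id"].isin(set(county_ids)).to_numpy()
    if years is not None:
        mask &= base["year"].isin(set(years)).to_numpy()
    return excess.shuffled(seed)[mask].sum(axis=0)


def compare_groups(
    a: np.ndarray, b: np.ndarray, seed: int = 0
) -> dict[str, float]:
    """Posterior probability that group A's excess exceeds group B's.

    Draw vectors are independently permuted (seeded), truncated to the
    shorter length and compared index-wise. Returns the strict fraction
    P(A > B), the tie fraction, and a tie-adjusted probability counting
    ties as 1/2.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty draw vector")
    n = min(a.size, b.size)
    ra = np.random.default_rng([seed, 1]).permutation(a.size)[:n]
    rb = np.random.default_rng([seed, 2]).permutation(b.size)[:n]
    av, bv = a[ra], b[rb]
    strict = float(np.mean(av > bv))
    ties = float(np.mean(av == bv))
    return {
        "prob_greater": strict,
        "tie_fraction": ties,
        "prob_greater_ties_half": strict + 0.5 * ties,
    }
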