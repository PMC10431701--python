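"""Excess summaries, grouped aggregation, tertiles and group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from stormexcess import aggregation as agg


def make_set(rows, draws):
    index = pd.DataFrame(rows, columns=["county_id", "year", "month"])
    return agg.ExcessDrawSet(index, np.asarray(draws, dtype=float))


class TestExcessDraws:
    def test_subtraction(self):
        out = agg.excess_draws(np.array([120.0]), np.array([[100.0, 110.0]]))
        assert out.tolist() == [[20.0, 10.0]]

    def test_point_mass_zero(self):
        out = agg.excess_draws(np.array([100.0]), np.full((1, 50), 100.0))
        assert np.all(out == 0)

    def test_linearity_of_means(self):
        rng = np.random.default_rng(0)
        obs = np.array([50.0, 70.0])
        cf = rng.poisson(60, size=(2, 400)).astype(float)
        out = agg.excess_draws(obs, cf)
        assert np.allclose(out.mean(axis=1), obs - cf.mean(axis=1))

    def test_missing_observed_rejected(self):
        with pytest.raises(ValueError, match="missing observed"):
            agg.excess_draws(np.array([np.nan]), np.zeros((1, 10)))


class TestSummarize:
    def test_degenerate_point_mass(self):
        s = agg.summarize(np.full(200, 7.0))
        assert (s.point_estimate, s.cri_low, s.cri_high) == (7.0, 7.0, 7.0)
        assert s.posterior_probability == 1.0

    def test_symmetric_draws_give_half_probability(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 20_000)
        s = agg.summarize(x)
        assert s.posterior_probability == pytest.approx(0.5, abs=0.02)

    def test_shifted_gaussian_matches_cdf_oracle(self):
        rng = np.random.default_rng(2)
        s = agg.summarize(rng.normal(0, 1, 10_000) + 1.0)
        assert s.posterior_probability == pytest.approx(norm.cdf(1.0), abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            agg.summarize(np.ones(50))


class TestAssignTertiles:
    def test_six_distinct_counties_split_two_each(self):
        svi = pd.DataFrame(
            {"county_id": list("ABCDEF"), "overall_pct": [0.1, 0.9, 0.3, 0.7, 0.5, 0.0]}
        )
        t = agg.assign_tertiles(svi)
        assert t.value_counts().tolist() == [2, 2, 2]
        assert t["F"] == 1 and t["B"] == 3

    def test_per_state_three_counties_one_per_tertile(self):
        svi = pd.DataFrame(
            {"county_id": ["A", "B", "C"], "overall_pct": [0.2, 0.8, 0.5]}
        )
        smap = pd.DataFrame({"county_id": ["A", "B", "C"], "state": "S1"})
        t = agg.assign_tertiles(svi, scope="per-state", state_map=smap)
        assert sorted(t.tolist()) == [1, 2, 3]

    def test_cutpoint_mode_uses_national_thirds(self):
        svi = pd.DataFrame(
            {"county_id": ["A", "B", "C", "D"], "overall_pct": [0.1, 0.2, 0.5, 0.9]}
        )
        t = agg.assign_tertiles(svi, mode="cutpoint")
        assert t.tolist() == [1, 1, 2, 3]  # unequal sizes allowed

    def test_rank_mode_breaks_ties_by_county_id(self):
        svi = pd.DataFrame(
            {"county_id": ["B", "A", "C"], "overall_pct": [0.5, 0.5, 0.5]}
        )
        t = agg.assign_tertiles(svi)
        assert t["A"] == 1 and t["B"] == 2 and t["C"] == 3

    def test_component_selection(self):
        svi = pd.DataFrame(
            {
                "county_id": ["A", "B", "C"],
                "overall_pct": [0.1, 0.5, 0.9],
                "minority_pct": [0.9, 0.5, 0.1],
            }
        )
        t = agg.assign_tertiles(svi, component="minority")
        assert t["A"] == 3 and t["C"] == 1


class TestAggregate:
    def test_point_mass_group_sum(self):
        es = make_set(
            [("A", 2000, 9), ("B", 2000, 9)],
            [np.full(200, 10.0), np.full(200, 20.0)],
        )
        out = agg.aggregate(es, ["national"])
        assert len(out) == 1
        assert out.loc[0, "point_estimate"] == 30.0
        assert out.loc[0, "posterior_probability"] == 1.0

    def test_probability_filter_drops_uncertain_members(self):
        rng = np.random.default_rng(5)
        sym = rng.normal(0, 1, 400)  # probability ~0.5
        es = make_set(
            [("A", 2000, 9), ("B", 2000, 9)],
            [sym, np.full(400, 15.0)],
        )
        out = agg.aggregate(es, ["national"], probability_filter=0.95)
        assert out.loc[0, "n_members"] == 1
        assert out.loc[0, "point_estimate"] == 15.0

    def test_county_state_national_sums_conserved(self):
        rng = np.random.default_rng(6)
        rows, draws = [], []
        for c in ["A", "B", "C", "D"]:
            for m in (8, 9):
                rows.append((c, 2001, m))
                draws.append(rng.normal(2, 5, 300))
        es = make_set(rows, draws)
        smap = pd.DataFrame(
            {"county_id": ["A", "B", "C", "D"], "state": ["S1", "S1", "S2", "S2"]}
        )
        seed = 17
        county = agg.aggregate(es, ["county", "year"], seed=seed)
        state = agg.aggregate(es, ["state", "year"], state_map=smap, seed=seed)
        nat = agg.aggregate(es, ["national", "year"], seed=seed)
        assert county["point_estimate"].sum() == pytest.approx(
            nat["point_estimate"].sum()
        )
        assert state["point_estimate"].sum() == pytest.approx(
            nat["point_estimate"].sum()
        )
        # exact conservation per draw index, not just in the mean
        shuffled = es.shuffled(seed)
        assert np.allclose(shuffled.sum(axis=0).mean(), nat["point_estimate"].sum())

    def test_filtered_totals_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        rows = [(f"C{i}", 2000 + i % 3, 9) for i in range(12)]
        draws = [rng.normal(rng.uniform(-2, 4), 3, 500) for _ in rows]
        es = make_set(rows, draws)
        counts = []
        for thr in (0.0, 0.5, 0.8, 0.95, 0.99):
            out = agg.aggregate(es, ["national"], probability_filter=thr)
            counts.append(int(out.loc[0, "n_members"]))
        assert counts == sorted(counts, reverse=True)

    def test_storm_grouping_splits_shared_months_by_weight(self):
        es = make_set([("A", 2000, 9)], [np.full(200, 10.0)])
        targets = pd.DataFrame(
            [
                ("A", 2000, 9, "X", "gale_to_violent_storm", "month_of", 0.5),
                ("A", 2000, 9, "Y", "hurricane", "month_after", 0.5),
            ],
            columns=["county_id", "year", "month", "storm_name", "category", "phase", "weight"],
        )
        out = agg.aggregate(es, ["storm"], targets=targets).set_index("storm")
        assert out.loc["X", "point_estimate"] == pytest.approx(5.0)
        assert out.loc["Y", "point_estimate"] == pytest.approx(5.0)

    def test_unknown_grouping_key_rejected(self):
        es = make_set([("A", 2000, 9)], [np.zeros(200)])
        with pytest.raises(ValueError, match="unknown grouping"):
            agg.aggregate(es, ["continent"])


class TestCompareGroups:
    def test_point_masses(self):
        out = agg.compare_groups(np.full(500, 10.0), np.full(500, 5.0))
        assert out["prob_greater"] == 1.0

    def test_identical_constant_vectors_tie(self):
        out = agg.compare_groups(np.full(500, 3.0), np.full(500, 3.0))
        assert out["prob_greater"] == 0.0
        assert out["tie_fraction"] == 1.0
        assert out["prob_greater_ties_half"] == 0.5

    def test_gaussian_difference_cdf_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.normal(2, 1, 10_000)
        b = rng.normal(0, 1, 10_000)
        out = agg.compare_groups(a, b, seed=1)
        expected = norm.cdf(2 / np.sqrt(2))
        assert out["prob_greater"] == pytest.approx(expected, abs=0.01)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            agg.compare_groups(np.array([]), np.ones(10))
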