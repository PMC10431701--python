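"""June-anchored population interpolation, anomalies and panel checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stormexcess import preprocess


def annual(county, series):
    return pd.DataFrame(
        [{"county_id": county, "year": y, "population": p} for y, p in series.items()]
    )


class TestInterpolatePopulation:
    def test_exact_at_june_anchors_and_midpoint(self):
        pop = preprocess.interpolate_population(annual("C1", {2000: 1200, 2001: 1212}))
        s = pop.set_index(["year", "month"])["population"]
        assert s.loc[(2000, 6)] == 1200
        assert s.loc[(2001, 6)] == 1212
        assert s.loc[(2000, 12)] == 1206  # midpoint of the June-June line

    def test_three_year_series_hand_checked(self):
        pop = preprocess.interpolate_population(
            annual("C1", {2000: 1200, 2001: 1212, 2002: 1236})
        )
        s = pop.set_index(["year", "month"])["population"]
        assert s.loc[(2001, 3)] == pytest.approx(1209)
        assert s.loc[(2001, 9)] == pytest.approx(1218)

    def test_constant_series_stays_constant(self):
        pop = preprocess.interpolate_population(annual("C1", {2000: 500, 2001: 500}))
        assert (pop["population"] == 500).all()

    def test_edges_extend_segment_slope(self):
        pop = preprocess.interpolate_population(annual("C1", {2000: 1200, 2001: 1212}))
        s = pop.set_index(["year", "month"])["population"]
        # Jan 2000 is 5 months before the June anchor on the first segment
        assert s.loc[(2000, 1)] == pytest.approx(1200 - 5 * 1.0)
        assert s.loc[(2001, 12)] == pytest.approx(1212 + 6 * 1.0)

    def test_linear_within_segment_second_differences_zero(self):
        pop = preprocess.interpolate_population(
            annual("C1", {2000: 1000, 2001: 1600, 2002: 1300})
        )
        v = pop["population"].to_numpy()
        d2 = np.diff(v, 2)
        # slope only changes at the June 2001 / June 2002 anchors
        # (month indices 17 and 29 -> second differences at 16 and 28)
        breaks = {16, 28}
        for i, val in enumerate(d2):
            if i not in breaks:
                assert abs(val) < 1e-9

    def test_missing_year_rejected(self):
        with pytest.raises(ValueError, match="missing years"):
            preprocess.interpolate_population(annual("C1", {2000: 100, 2002: 120}))

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            preprocess.interpolate_population(annual("C1", {2000: 0, 2001: 10}))

    def test_outputs_floored_above_zero(self):
        pop = preprocess.interpolate_population(annual("C1", {2000: 200, 2001: 2}))
        assert (pop["population"] >= 1).all()


def _panel_from_temps(temps):
    rows = []
    for (y, m), t in temps.items():
        rows.append(
            dict(county_id="C1", year=y, month=m, temperature=t)
        )
    return pd.DataFrame(rows)


class TestAnomaly:
    def test_identical_januaries_have_zero_anomaly(self):
        panel = _panel_from_temps({(2000, 1): 4.0, (2001, 1): 4.0, (2002, 1): 4.0})
        out = preprocess.compute_anomaly(panel)
        assert np.allclose(out["anomaly"], 0.0)

    def test_two_point_mean(self):
        panel = _panel_from_temps({(2000, 1): 4.0, (2001, 1): 6.0})
        out = preprocess.compute_anomaly(panel).set_index("year")["anomaly"]
        assert out.loc[2000] == -1.0 and out.loc[2001] == 1.0

    def test_idempotent(self):
        panel = _panel_from_temps({(2000, 1): 4.0, (2001, 1): 6.0, (2000, 2): 9.0})
        once = preprocess.compute_anomaly(panel)
        twice = preprocess.compute_anomaly(once)
        pd.testing.assert_frame_equal(once, twice)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_mean_zero_identity_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for county in ("A", "B"):
            for y in range(2000, 2000 + int(rng.integers(2, 6))):
                for m in range(1, 13):
                    rows.append(
                        dict(county_id=county, year=y, month=m,
                             temperature=float(rng.normal(15, 8)))
                    )
        out = preprocess.compute_anomaly(pd.DataFrame(rows))
        means = out.groupby(["county_id", "month"])["anomaly"].mean()
        assert means.abs().max() < 1e-9


class TestDeathRate:
    def test_arithmetic_and_inverse(self):
        panel = pd.DataFrame(
            dict(deaths=[0, 30], population=[100.0, 60000.0])
        )
        rate = preprocess.death_rate(panel)
        assert rate.iloc[0] == 0
        assert rate.iloc[1] == pytest.approx(5e-4)
        assert np.allclose(rate * panel["population"], panel["deaths"])

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            preprocess.death_rate(pd.DataFrame(dict(deaths=[1], population=[0.0])))


def test_check_grid_rejects_gaps():
    rows = [
        dict(county_id="C1", year=2000, month=m, deaths=1) for m in range(1, 13)
    ] + [dict(county_id="C2", year=2000, month=m, deaths=1) for m in range(1, 12)]
    with pytest.raises(ValueError, match="rectangular"):
        preprocess.check_grid(pd.DataFrame(rows))


def test_build_panel_round_trip(small_quiet_panel):
    _, panel, _, _ = small_quiet_panel
    deaths = panel[["county_id", "year", "month", "deaths"]]
    temps = panel[["county_id", "year", "month", "temperature"]].rename(
        columns={"temperature": "temp_c"}
    )
    years = sorted(panel["year"].unique())
    pop = panel.query("month == 6")[["county_id", "year", "population"]]
    rebuilt = preprocess.build_panel(deaths, pop, temps)
    assert len(rebuilt) == len(panel)
    # June populations are anchors, so they reproduce exactly
    merged = rebuilt.query("month == 6").merge(
        panel.query("month == 6"), on=["county_id", "year", "month"]
    )
    assert np.allclose(merged["population_x"], merged["population_y"])
    assert np.allclose(rebuilt["anomaly"], panel["anomaly"])
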