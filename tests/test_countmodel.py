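"""Ensemble spec grid, linear predictor arithmetic, and fit oracles."""

import copy

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import ks_2samp

import stormexcess as se
from stormexcess.countmodel import FitConfig, ModelSpec, enumerate_specs, linear_predictor


class TestSpecGrid:
    def test_sixteen_unique_specs(self):
        specs = enumerate_specs()
        assert len(specs) == 16
        assert len({(s.include_trend, s.ar_order, s.include_temperature) for s in specs}) == 16
        assert [s.model_id for s in specs] == list(range(1, 17))

    def test_grid_combinatorics(self):
        specs = enumerate_specs()
        assert sum(s.include_trend for s in specs) == 8
        assert sum(s.ar_order == 6 for s in specs) == 4
        assert sum(s.include_temperature for s in specs) == 8

    def test_deterministic_ordering(self):
        specs = enumerate_specs()
        # trend-major, then AR order ascending, then temperature
        assert (specs[0].include_trend, specs[0].ar_order, specs[0].include_temperature) == (False, 1, False)
        assert (specs[1].include_trend, specs[1].ar_order, specs[1].include_temperature) == (False, 1, True)
        assert specs[8].include_trend is True


class TestLinearPredictor:
    def test_offset_arithmetic(self):
        spec = ModelSpec(1, False, 1, False)
        eta = linear_predictor(
            spec, {"alpha0": np.log(5e-4)}, month=3, time_index=10,
            anomaly=0.0, population=60_000,
        )
        assert np.exp(eta) == pytest.approx(30.0)

    def test_doubling_population_doubles_mean(self):
        spec = ModelSpec(1, False, 1, False)
        base = dict(alpha0=-7.0, theta=np.full(12, 0.01) - 0.01)
        e1 = linear_predictor(spec, base, 5, 0, 0.0, 50_000)
        e2 = linear_predictor(spec, base, 5, 0, 0.0, 100_000)
        assert np.exp(e2) == pytest.approx(2 * np.exp(e1))

    def test_temperature_terms_add_as_printed(self):
        spec = ModelSpec(2, False, 1, True)
        params = {"alpha0": -7.0, "gamma": 0.01, "nu": np.full(12, 0.002)}
        hot = linear_predictor(spec, params, 7, 0, 2.0, 10_000)
        cold = linear_predictor(spec, params, 7, 0, 0.0, 10_000)
        assert hot - cold == pytest.approx((0.01 + 0.002) * 2.0)

    def test_excluded_terms_are_forced_to_zero(self):
        spec = ModelSpec(1, False, 1, False)
        params = {"alpha0": -7.0, "gamma": 5.0, "beta": 5.0}
        with_terms = linear_predictor(spec, params, 1, 10, 3.0, 10_000)
        without = linear_predictor(spec, {"alpha0": -7.0}, 1, 10, 3.0, 10_000)
        assert with_terms == pytest.approx(without)

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            linear_predictor(ModelSpec(1, False, 1, False), {}, 1, 0, 0.0, 0.0)


@pytest.fixture(scope="module")
def one_county_panel():
    cfg = se.SimConfig(
        n_counties=1, n_years=10, storm_rate=0.0, seed=21,
        ar_coeffs=(0.4,), ar_sd=0.03, overdispersion_sd=0.02,
        pop_range=(1e5, 2e5),
    )
    panel, _, _ = se.generate_panel(cfg)
    return cfg, panel


class TestDegenerateFit:
    def test_matches_closed_form_poisson_mle(self, one_county_panel):
        """With random effects off and no trend/temperature, the posterior
        rate equals the closed-form Poisson MLE within 2%."""
        _, panel = one_county_panel
        spec = ModelSpec(1, False, 1, False)
        cfg = FitConfig(random_effects=False)
        res = se.model_from_panel(panel, spec, "C0001", config=cfg).fit()
        mle = panel["deaths"].sum() / panel["population"].sum()
        sd = res.latent_sd("alpha0")[0]
        post_mean_rate = np.exp(res.params["alpha0"] + 0.5 * sd**2)
        assert post_mean_rate == pytest.approx(mle, rel=0.02)

    def test_matches_statsmodels_glm(self, one_county_panel):
        """Cross-check the degenerate fit against an independent Poisson GLM
        with a log-population offset."""
        _, panel = one_county_panel
        spec = ModelSpec(1, False, 1, False)
        cfg = FitConfig(random_effects=False)
        res = se.model_from_panel(panel, spec, "C0001", config=cfg).fit()
        glm = sm.GLM(
            panel["deaths"].to_numpy(),
            np.ones((len(panel), 1)),
            family=sm.families.Poisson(),
            offset=np.log(panel["population"].to_numpy()),
        ).fit()
        assert res.params["alpha0"] == pytest.approx(glm.params[0], abs=1e-4)
        assert res.latent_sd("alpha0")[0] == pytest.approx(glm.bse[0], rel=0.05)


@pytest.fixture(scope="module")
def fitted_with_holdout():
    """AR(1)+temperature fit with two same-calendar-month holdouts."""
    cfg = se.SimConfig(
        n_counties=1, n_years=10, storm_rate=0.0, seed=33,
        ar_coeffs=(0.5,), ar_sd=0.03, overdispersion_sd=0.02,
        pop_range=(1e5, 2e5),
    )
    panel, _, _ = se.generate_panel(cfg)
    sub = panel[panel["county_id"] == "C0001"]
    # hold out January of years 4 and 7 (same calendar month, mid-panel)
    hold = ((sub["month"] == 1) & sub["year"].isin([cfg.start_year + 3, cfg.start_year + 6])).to_numpy()
    spec = ModelSpec(2, False, 1, True)
    model = se.model_from_panel(panel, spec, "C0001", extra_holdout=hold, config=FitConfig())
    return model, model.fit(), np.where(hold)[0]


class TestPrediction:
    def test_halving_population_offset_halves_mean(self, fitted_with_holdout):
        model, res, hold_idx = fitted_with_holdout
        rng = np.random.default_rng(0)
        base = res.predict_counterfactual(hold_idx, 4000, rng)
        res2 = copy.deepcopy(res)
        res2.model.offset = res2.model.offset - np.log(2.0)
        rng = np.random.default_rng(0)
        halved = res2.predict_counterfactual(hold_idx, 4000, rng)
        ratio = halved.mean() / base.mean()
        assert ratio == pytest.approx(0.5, rel=0.03)

    def test_draws_are_nonnegative_integers(self, fitted_with_holdout):
        _, res, hold_idx = fitted_with_holdout
        draws = res.predict_counterfactual(hold_idx, 500, np.random.default_rng(1))
        assert draws.dtype.kind == "i" and (draws >= 0).all()
        assert draws.shape == (len(hold_idx), 500)

    def test_heldout_months_with_same_covariates_are_exchangeable(
        self, fitted_with_holdout
    ):
        """Two held-out months of the same calendar month should have
        counterfactual distributions that a KS test cannot tell apart
        (after matching their population offsets and anomalies)."""
        model, res, hold_idx = fitted_with_holdout
        res2 = copy.deepcopy(res)
        # equalise offsets and anomaly columns at the two held-out months
        i, j = hold_idx
        res2.model.offset[j] = res2.model.offset[i]
        res2.model.D[j] = res2.model.D[i]
        draws = res2.predict_counterfactual([i, j], 1000, np.random.default_rng(2))
        stat = ks_2samp(draws[0], draws[1])
        assert stat.pvalue > 0.01


class TestRecoverySmoke:
    def test_ar1_and_gamma_recovered_roughly(self):
        """Single-replicate sanity check of parameter recovery (the full
        multi-replicate coverage study lives in the acceptance suite)."""
        cfg = se.SimConfig(
            n_counties=1, n_years=16, storm_rate=0.0, seed=77,
            ar_coeffs=(0.6,), ar_sd=0.05, overdispersion_sd=0.02,
            temp_effect=0.01, pop_range=(3e5, 6e5),
        )
        panel, _, _ = se.generate_panel(cfg)
        spec = ModelSpec(2, False, 1, True)
        res = se.model_from_panel(panel, spec, "C0001").fit()
        assert res.converged
        assert res.params["phi"][0] == pytest.approx(0.6, abs=0.3)
        mean, lo, hi = res.fixed_effect_interval("gamma")
        assert hi - lo < 0.05  # informative
        assert abs(mean - 0.01) < 0.02


def test_too_few_training_months_rejected():
    cfg = se.SimConfig(n_counties=1, n_years=2, storm_rate=0.0, seed=1)
    panel, _, _ = se.generate_panel(cfg)
    hold = np.ones(24, dtype=bool)
    hold[:10] = False  # leaves only 10 training months
    with pytest.raises(ValueError, match="training months"):
        se.model_from_panel(panel, ModelSpec(1, False, 1, False), "C0001", extra_holdout=hold)
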