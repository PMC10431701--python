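"""Synthetic county-month panels with known ground truth.

The generator emulates the statistical structure the ensemble assumes:
winter-peaked seasonality of death rates, a slow log-linear trend,
month-to-month autocorrelation (stationary AR on the log rate, simulated
through the same partial-autocorrelation parameterisation the fitter uses),
temperature-anomaly effects with a smooth month-specific modifier, i.i.d.
log-normal overdispersion, storm calendars concentrated in May-November
with a September mode, and multiplicative excess mortality injected in the
month of and the month after each exposure. Exposure calendars are produced
by running the exposure classifier on the simulated daily peak winds, so
simulator and pipeline can never disagree about what counts as exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from . import exposure, preprocess, priors

#: storm occurrence weights for May..November (September mode, mimicking
#: the observed seasonality of U.S. landfalling tropical cyclones)
STORM_MONTHS = np.arange(5, 12)
STORM_MONTH_WEIGHTS = np.array([2.0, 4.0, 7.0, 12.0, 30.0, 15.0, 5.0])

TRUTH_COLUMNS = [
    "county_id",
    "year",
    "month",
    "latent_log_mean",
    "injected_excess",
    "category",
]


def _default_seasonal() -> tuple:
    m = np.arange(12)
    amp = np.exp(0.08 * np.cos(2 * np.pi * m / 12.0))
    return tuple(amp / np.exp(np.mean(np.log(amp))))


def _default_month_temp() -> tuple:
    m = np.arange(12)
    return tuple(0.003 * np.cos(2 * np.pi * m / 12.0))


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Rates are on the per-person-month scale; all log-rate effects are
    additive on the log link. Default values describe a mid-sized U.S.
    county panel: a crude death rate of 7.5e-4 per person-month (~9 per
    1000 per year), ~8% winter/summer seasonal swing, a slowly declining
    trend, AR(1) month-to-month correlation 0.5, a 0.5%-per-degree
    temperature-anomaly effect with a smooth seasonal modifier, mild
    overdispersion, 0.3 storms per county-year with ~5% of storm winds
    reaching hurricane force, and a 25% mortality increase in both the
    month of and the month after exposure.
    """

    n_counties: int = 40
    n_years: int = 16
    start_year: int = 2000
    baseline_rate: float = 7.5e-4
    seasonal_amplitudes: tuple = field(default_factory=_default_seasonal)
    trend_slope: float = -0.0002
    ar_order: int = 1
    ar_coeffs: tuple = (0.5,)
    ar_sd: float = 0.02
    temp_effect: float = 0.005
    month_temp_effects: tuple = field(default_factory=_default_month_temp)
    overdispersion_sd: float = 0.02
    storm_rate: float = 0.3
    wind_distribution: dict = field(
        default_factory=lambda: {"min": 34.0, "scale": 10.0}
    )
    excess_multiplier_month0: float = 1.25
    excess_multiplier_month1: float = 1.25
    seed: int = 0
    # population and temperature scenery
    pop_range: tuple = (2e4, 3e5)
    pop_growth_range: tuple = (0.0, 0.01)
    temp_mean: float = 18.0
    temp_seasonal_amplitude: float = 10.0
    temp_noise_sd: float = 1.5

    def validate(self) -> None:
        if self.n_counties < 1 or self.n_years < 2:
            raise ValueError("need n_counties >= 1 and n_years >= 2")
        if len(self.seasonal_amplitudes) != 12:
            raise ValueError("seasonal_amplitudes must have length 12")
        if len(self.month_temp_effects) != 12:
            raise ValueError("month_temp_effects must have length 12")
        if abs(sum(self.month_temp_effects)) > 1e-8:
            raise ValueError("month_temp_effects must sum to 0")
        if len(self.ar_coeffs) != self.ar_order:
            raise ValueError("ar_coeffs must have length ar_order")
        if self.ar_order and np.any(np.abs(np.asarray(self.ar_coeffs)) >= 1.0):
            raise ValueError("ar_coeffs are partial autocorrelations in (-1, 1)")
        for name in ("ar_sd", "overdispersion_sd", "storm_rate", "baseline_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("excess_multiplier_month0", "excess_multiplier_month1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _county_ids(n: int) -> list[str]:
    return [f"C{i:04d}" for i in range(1, n + 1)]


def _simulate_ar(
    order: int, pacf: np.ndarray, innov_sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if order == 0 or innov_sd == 0.0:
        return np.zeros(n)
    pacf = np.asarray(pacf, dtype=float)
    phi = priors.pacf_to_ar(pacf)
    marg_var = innov_sd**2 / np.prod(1.0 - pacf**2)
    acovf = priors._stationary_acovf(pacf, marg_var, order)
    L = np.linalg.cholesky(toeplitz(acovf))
    z = np.empty(n)
    z[:order] = L @ rng.standard_normal(order)
    innov = rng.normal(0.0, innov_sd, size=n)
    for t in range(order, n):
        z[t] = phi @ z[t - order : t][::-1] + innov[t]
    return z


def generate_wind_records(
    config: SimConfig, county_ids: list[str], seeds
) -> pd.DataFrame:
    """Simulated daily peak sustained winds: one single-day record per storm."""
    rows = []
    wd = config.wind_distribution
    pweights = STORM_MONTH_WEIGHTS / STORM_MONTH_WEIGHTS.sum()
    for county, ss in zip(county_ids, seeds):
        rng = np.random.default_rng(ss)
        n_storms = rng.poisson(config.storm_rate * config.n_years)
        for k in range(n_storms):
            year = config.start_year + int(rng.integers(config.n_years))
            month = int(rng.choice(STORM_MONTHS, p=pweights))
            day = int(rng.integers(1, 29))
            wind = float(wd["min"] + rng.exponential(wd["scale"]))
            rows.append(
                dict(
                    county_id=county,
                    date=f"{year:04d}-{month:02d}-{day:02d}",
                    storm_name=f"ST_{county}_{k + 1}",
                    wind_knots=round(wind, 1),
                )
            )
    return pd.DataFrame(rows, columns=exposure.WIND_COLUMNS)


def generate_annual_population(
    config: SimConfig, county_ids: list[str], seeds
) -> pd.DataFrame:
    rows = []
    lo, hi = config.pop_range
    glo, ghi = config.pop_growth_range
    for county, ss in zip(county_ids, seeds):
        rng = np.random.default_rng(ss)
        p0 = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        g = rng.uniform(glo, ghi)
        for j in range(config.n_years):
            rows.append(
                dict(
                    county_id=county,
                    year=config.start_year + j,
                    population=int(round(p0 * (1.0 + g) ** j)),
                )
            )
    return pd.DataFrame(rows)


def generate_temperature(
    config: SimConfig, county_ids: list[str], seeds
) -> pd.DataFrame:
    rows = []
    for county, ss in zip(county_ids, seeds):
        rng = np.random.default_rng(ss)
        base = config.temp_mean + rng.uniform(-4.0, 4.0)
        for j in range(config.n_years):
            for m in range(1, 13):
                temp = (
                    base
                    - config.temp_seasonal_amplitude * np.cos(2 * np.pi * (m - 7) / 12.0)
                    + rng.normal(0.0, config.temp_noise_sd)
                )
                rows.append(
                    dict(
                        county_id=county,
                        year=config.start_year + j,
                        month=m,
                        temp_c=round(float(temp), 3),
                    )
                )
    return pd.DataFrame(rows)


def _streams(config: SimConfig) -> tuple[list[str], list]:
    ids = _county_ids(config.n_counties)
    root = np.random.SeedSequence(config.seed)
    county_seeds = root.spawn(config.n_counties)
    # per-county sub-streams: pop, temp, ar, eps, storm, deaths
    return ids, [s.spawn(6) for s in county_seeds]


def generate_panel(
    config: SimConfig,
) -> tuple[pd.DataFrame, exposure.ExposureCalendar, pd.DataFrame]:
    """Generate (panel, exposure calendar, truth record).

    The panel covers every county-month of [start_year, start_year+n_years);
    deaths are Poisson draws around a latent log mean combining population
    offset, baseline rate, seasonality, trend, AR noise, temperature-anomaly
    effects, overdispersion, and the log excess multiplier in exposed
    windows. The truth record carries the latent log mean without the storm
    effect, the expected injected excess, and the frozen exposure category.
    Identical seeds give identical output.
    """
    config.validate()
    ids, streams = _streams(config)

    annual_pop = generate_annual_population(config, ids, [s[0] for s in streams])
    temp = generate_temperature(config, ids, [s[1] for s in streams])
    wind = generate_wind_records(config, ids, [s[4] for s in streams])
    span_lo = (config.start_year, 1)
    span_hi = (config.start_year + config.n_years - 1, 12)
    calendar = exposure.build_calendar(wind, span_lo, span_hi)

    pop_monthly = preprocess.interpolate_population(annual_pop, span_lo, span_hi)
    base = pop_monthly.merge(
        temp.rename(columns={"temp_c": "temperature"}),
        on=["county_id", "year", "month"],
    )
    base = preprocess.compute_anomaly(base)
    base["time_index"] = (base["year"] - config.start_year) * 12 + base["month"] - 1
    base = base.sort_values(["county_id", "time_index"]).reset_index(drop=True)

    cat_lookup = calendar.category_lookup()
    target_keys = set(map(tuple, calendar.target_months().to_numpy()))

    T = config.n_years * 12
    seasonal = np.log(np.asarray(config.seasonal_amplitudes, dtype=float))
    month_dev = np.asarray(config.month_temp_effects, dtype=float)
    log_base = np.log(config.baseline_rate)

    frames = []
    truth_frames = []
    for county, st in zip(ids, streams):
        sub = base[base["county_id"] == county]
        rng_ar = np.random.default_rng(st[2])
        rng_eps = np.random.default_rng(st[3])
        rng_deaths = np.random.default_rng(st[5])
        m = sub["month"].to_numpy()
        t = sub["time_index"].to_numpy()
        anom = sub["anomaly"].to_numpy()
        zeta = _simulate_ar(
            config.ar_order, np.asarray(config.ar_coeffs), config.ar_sd, T, rng_ar
        )
        eps = (
            rng_eps.normal(0.0, config.overdispersion_sd, size=T)
            if config.overdispersion_sd > 0
            else np.zeros(T)
        )
        log_rate = (
            log_base
            + seasonal[m - 1]
            + config.trend_slope * t
            + zeta
            + (config.temp_effect + month_dev[m - 1]) * anom
            + eps
        )
        latent = np.log(sub["population"].to_numpy()) + log_rate

        log_mult = np.zeros(T)
        categories = np.full(T, exposure.NONE, dtype=object)
        for i, (yy, mm) in enumerate(zip(sub["year"].to_numpy(), m)):
            key = (county, int(yy), int(mm))
            cat = cat_lookup.get(key, exposure.NONE)
            categories[i] = cat
            if cat != exposure.NONE:
                log_mult[i] = np.log(config.excess_multiplier_month0)
            elif key in target_keys:
                log_mult[i] = np.log(config.excess_multiplier_month1)

        deaths = rng_deaths.poisson(np.exp(latent + log_mult))
        frames.append(
            pd.DataFrame(
                {
                    "county_id": county,
                    "year": sub["year"].to_numpy(),
                    "month": m,
                    "deaths": deaths,
                    "population": sub["population"].to_numpy(),
                    "temperature": sub["temperature"].to_numpy(),
                    "anomaly": anom,
                    "time_index": t,
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "county_id": county,
                    "year": sub["year"].to_numpy(),
                    "month": m,
                    "latent_log_mean": latent,
                    "injected_excess": np.exp(latent) * (np.exp(log_mult) - 1.0),
                    "category": categories,
                }
            )
        )

    panel = pd.concat(frames, ignore_index=True)[preprocess.PANEL_COLUMNS]
    truth = pd.concat(truth_frames, ignore_index=True)[TRUTH_COLUMNS]
    return panel, calendar, truth


def generate_bundle(config: SimConfig, svi_seed: int | None = None) -> dict:
    """Panel, calendar and truth plus the raw input tables the pipeline
    reads (deaths, annual population, temperature, wind, SVI, state map),
    all deterministic under config.seed."""
    panel, calendar, truth = generate_panel(config)
    ids, streams = _streams(config)
    return {
        "panel": panel,
        "calendar": calendar,
        "truth": truth,
        "deaths": panel[["county_id", "year", "month", "deaths"]],
        "population": generate_annual_population(config, ids, [s[0] for s in streams]),
        "temperature": panel[["county_id", "year", "month", "temperature"]].rename(
            columns={"temperature": "temp_c"}
        ),
        "wind": generate_wind_records(config, ids, [s[4] for s in streams]),
        "svi": generate_svi_table(
            config.n_counties, config.seed if svi_seed is None else svi_seed
        ),
        "state_map": generate_state_map(config.n_counties),
    }


def generate_svi_table(n_counties: int, seed: int) -> pd.DataFrame:
    """Synthetic social-vulnerability percentiles.

    Overall plus the four component percentiles (socioeconomic status,
    household characteristics, racial and ethnic minority status, housing
    type and transportation); each column is an independent permutation of
    evenly spaced ranks in [0, 1]. Deterministic under the seed.
    """
    if n_counties < 3:
        raise ValueError("need at least 3 counties for tertiles")
    rng = np.random.default_rng(seed)
    ranks = np.linspace(0.0, 1.0, n_counties)
    cols = {}
    for name in (
        "overall_pct",
        "ses_pct",
        "household_pct",
        "minority_pct",
        "housing_transport_pct",
    ):
        cols[name] = rng.permutation(ranks)
    out = pd.DataFrame({"county_id": _county_ids(n_counties), **cols})
    return out


def generate_state_map(
    n_counties: int, counties_per_state: int = 5
) -> pd.DataFrame:
    """Round-robin assignment of counties to synthetic states and regions."""
    regions = ["southeast", "south", "northeast", "central"]
    rows = []
    for i, county in enumerate(_county_ids(n_counties)):
        s = i // counties_per_state
        rows.append(
            dict(county_id=county, state=f"S{s + 1:02d}", region=regions[s % 4])
        )
    return pd.DataFrame(rows)
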