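"""Bayesian monthly death-count models and their Laplace-approximate fits.

Each ensemble member models a single county's monthly all-cause deaths as

    deaths_t ~ Poisson(exp(eta_t))
    eta_t = alpha0 + theta_{m(t)} + zeta_t + (beta + omega_{m(t)}) * time_t
            + (gamma + nu_{m(t)}) * anomaly_t + log(population_t) + eps_t

with a seasonal month intercept theta (intrinsic period-12 structure, fitted
with a hard sum-to-zero constraint), a stationary AR latent series zeta of
order 1, 2, 4 or 6 parameterised through partial autocorrelations, a
seasonal slope omega paired with the linear trend beta, a circular RW1 month
effect nu modifying the overall temperature-anomaly slope gamma, and i.i.d.
overdispersion eps on training months. Fixed effects get N(0, 1000) priors;
every precision a Gamma(0.001, 0.001) prior (log-Gamma on the log
precision); each transformed partial autocorrelation an N(0, 1) prior.

The 16-member ensemble is the 2 (trend) x 4 (AR order) x 2 (temperature)
grid of these models.

Fitting is empirical-Bayes Laplace: for a candidate hyperparameter vector
the latent Gaussian field is maximised by Newton iterations (the
log-likelihood runs over training months only; target months' latent states
are propagated through their priors), the Laplace approximation of the
marginal posterior of the hyperparameters is optimised numerically, and
posterior draws come from the Gaussian approximation at the joint mode.
Internally zeta and eps are carried as one residual component u_t with
covariance Sigma_AR + sigma_eps^2 * 1[t in training] — an exact
reformulation that halves the latent dimension; at unobserved months u_t is
the propagated AR state alone. Counterfactual counts for target months are
posterior-predictive draws with a freshly drawn overdispersion term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular, toeplitz

from . import priors

AR_ORDERS = (1, 2, 4, 6)
FIXED_PRIOR_VARIANCE = 1000.0
MIN_TRAINING_MONTHS = 24


@dataclass(frozen=True)
class ModelSpec:
    """One member of the 2 x 4 x 2 model grid."""

    model_id: int
    include_trend: bool
    ar_order: int
    include_temperature: bool

    @property
    def label(self) -> str:
        return (
            f"M{self.model_id:02d}(trend={'+' if self.include_trend else '-'},"
            f"ar={self.ar_order},temp={'+' if self.include_temperature else '-'})"
        )


def enumerate_specs() -> list[ModelSpec]:
    """The 16 model specifications, trend-major, then AR order, then
    temperature."""
    specs = []
    i = 1
    for trend in (False, True):
        for p in AR_ORDERS:
            for temp in (False, True):
                specs.append(ModelSpec(i, trend, p, temp))
                i += 1
    return specs


@dataclass
class FitConfig:
    """Knobs of the Laplace fit.

    time_scale divides the month index for numeric conditioning (the trend
    slope is reported per month after unscaling). random_effects=False
    collapses the model to its fixed effects (used by degenerate closed-form
    checks); overdispersion=False drops the i.i.d. eps term.
    """

    n_draws: int = 1000
    time_scale: float = 120.0
    random_effects: bool = True
    overdispersion: bool = True
    max_outer_iter: int = 40
    outer_ftol: float = 1e-8
    fd_eps: float = 1e-4
    newton_tol: float = 1e-9
    max_newton_iter: int = 100
    hyper_bound: float = 16.0
    init_hyper: dict | None = None


def linear_predictor(
    spec: ModelSpec,
    params: dict,
    month: int,
    time_index: float,
    anomaly: float,
    population: float,
) -> float:
    """Evaluate log E[deaths] for one county-month from named parameters.

    ``params`` holds alpha0 and optionally beta, gamma, theta (12), omega
    (12), nu (12), zeta, eps; terms that the spec excludes are forced to
    zero. time_index is in months.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    m = int(month) - 1
    theta = np.asarray(params.get("theta", np.zeros(12)))
    eta = params.get("alpha0", 0.0) + theta[m] + params.get("zeta", 0.0)
    if spec.include_trend:
        omega = np.asarray(params.get("omega", np.zeros(12)))
        eta += (params.get("beta", 0.0) + omega[m]) * time_index
    if spec.include_temperature:
        nu = np.asarray(params.get("nu", np.zeros(12)))
        eta += (params.get("gamma", 0.0) + nu[m]) * anomaly
    eta += np.log(population) + params.get("eps", 0.0)
    return float(eta)


class MonthlyDeathModel:
    """Monthly death counts for one county under one ensemble spec.

    Parameters
    ----------
    deaths, month, time_index, population, anomaly : aligned arrays over the
        county's complete month grid (time_index consecutive).
    spec : ModelSpec
    train_mask : bool array; False rows (counterfactual targets, validation
        holdouts) are excluded from the likelihood but their latent states
        remain in the field.
    """

    def __init__(
        self,
        deaths,
        month,
        time_index,
        population,
        anomaly,
        spec: ModelSpec,
        train_mask=None,
        config: FitConfig | None = None,
        county_id=None,
    ):
        self.spec = spec
        self.config = config or FitConfig()
        self.county_id = county_id
        self.y = np.asarray(deaths, dtype=float)
        self.month = np.asarray(month, dtype=int)
        self.time_index = np.asarray(time_index, dtype=float)
        self.population = np.asarray(population, dtype=float)
        self.anomaly = np.asarray(anomaly, dtype=float)
        self.T = self.y.size
        if np.any(self.population <= 0):
            raise ValueError("population must be positive")
        if np.any(np.diff(self.time_index) != 1):
            raise ValueError("county series must cover consecutive months")
        if train_mask is None:
            train_mask = np.ones(self.T, dtype=bool)
        self.train_mask = np.asarray(train_mask, dtype=bool)
        self.n_train = int(self.train_mask.sum())
        if self.n_train < MIN_TRAINING_MONTHS:
            raise ValueError(
                f"only {self.n_train} unexposed training months; "
                f"need at least {MIN_TRAINING_MONTHS}"
            )
        self.offset = np.log(self.population)
        self._build_design()

    # ------------------------------------------------------------------ #
    def _build_design(self) -> None:
        cfg = self.config
        spec = self.spec
        T = self.T
        u_time = (self.time_index - self.time_index[0]) / cfg.time_scale
        self._scaled_time = u_time
        M = np.zeros((T, 12))
        M[np.arange(T), self.month - 1] = 1.0
        Z = priors.sum_to_zero_basis(12)
        self._Z12 = Z

        cols: list[np.ndarray] = []
        slices: dict[str, slice] = {}
        pos = 0

        def add(name, block):
            nonlocal pos
            cols.append(block)
            slices[name] = slice(pos, pos + block.shape[1])
            pos += block.shape[1]

        add("alpha0", np.ones((T, 1)))
        if spec.include_trend:
            add("beta", u_time[:, None])
        if spec.include_temperature:
            add("gamma", self.anomaly[:, None])

        self._hyper_names: list[str] = []
        if cfg.random_effects:
            MZ = M @ Z
            add("theta", MZ)
            self._hyper_names.append("log_tau_theta")
            if spec.include_trend:
                add("omega", MZ * u_time[:, None])
                self._hyper_names.append("log_tau_omega")
            if spec.include_temperature:
                add("nu", MZ * self.anomaly[:, None])
                self._hyper_names.append("log_tau_nu")
            self._hyper_names.append("ar_kappa1")
            self._hyper_names += [f"ar_kappa2_{j}" for j in range(1, spec.ar_order + 1)]
            if cfg.overdispersion:
                self._hyper_names.append("log_tau_eps")

        self.D = np.hstack(cols)
        self.k = self.D.shape[1]
        self.has_u = cfg.random_effects
        self.slices = slices
        self.n_latent = self.k + (T if self.has_u else 0)
        Rz = Z.T @ priors.circular_rw1_structure(12) @ Z
        self._Rz = Rz
        _, self._logdet_Rz = np.linalg.slogdet(Rz)

    # ------------------------------------------------------------------ #
    def _default_hyper_init(self) -> np.ndarray:
        defaults = {
            "log_tau_theta": 5.0,
            "log_tau_omega": 8.0,
            "log_tau_nu": 8.0,
            "ar_kappa1": 6.0,
            "log_tau_eps": 7.0,
        }
        init = []
        user = self.config.init_hyper or {}
        for name in self._hyper_names:
            if name in user:
                init.append(user[name])
            elif name.startswith("ar_kappa2"):
                init.append(user.get("ar_kappa2", 0.5 if name.endswith("_1") else 0.0))
            else:
                init.append(defaults[name])
        return np.array(init)

    def _prior_blocks(self, h: np.ndarray):
        """(Q_dd, Q_u, logdet of the joint prior precision) for hypers h.

        The u covariance is Sigma_AR(T) + sigma_eps^2 on training months;
        its precision comes from a Cholesky solve.
        """
        hv = dict(zip(self._hyper_names, h))
        Q_dd = np.zeros((self.k, self.k))
        logdet = 0.0
        for kname in ("alpha0", "beta", "gamma"):
            if kname in self.slices:
                s = self.slices[kname]
                Q_dd[s, s] = 1.0 / FIXED_PRIOR_VARIANCE
                logdet += -np.log(FIXED_PRIOR_VARIANCE)
        for kname, hname in (("theta", "log_tau_theta"), ("omega", "log_tau_omega")):
            if kname in self.slices and hname in hv:
                s = self.slices[kname]
                Q_dd[s, s] = np.exp(hv[hname]) * np.eye(11)
                logdet += 11 * hv[hname]
        if "nu" in self.slices and "log_tau_nu" in hv:
            s = self.slices["nu"]
            Q_dd[s, s] = np.exp(hv["log_tau_nu"]) * self._Rz
            logdet += 11 * hv["log_tau_nu"] + self._logdet_Rz

        Q_u = None
        if self.has_u:
            pacf = priors.kappa_to_pacf(
                np.array(
                    [hv[f"ar_kappa2_{j}"] for j in range(1, self.spec.ar_order + 1)]
                )
            )
            pacf = np.clip(pacf, -0.995, 0.995)
            marg_var = np.exp(-hv["ar_kappa1"])
            acovf = priors._stationary_acovf(pacf, marg_var, self.T)
            sigma_u = toeplitz(acovf)
            if "log_tau_eps" in hv:
                idx = np.where(self.train_mask)[0]
                sigma_u[idx, idx] += np.exp(-hv["log_tau_eps"])
            c = cho_factor(sigma_u, lower=True, check_finite=False)
            Q_u = cho_solve(c, np.eye(self.T), check_finite=False)
            logdet += -2.0 * float(np.sum(np.log(np.diag(c[0]))))
        return Q_dd, Q_u, logdet

    def _hyper_log_prior(self, h: np.ndarray) -> float:
        lp = 0.0
        for name, val in zip(self._hyper_names, h):
            if name.startswith("ar_kappa2"):
                lp += -0.5 * val**2
            else:
                # Gamma(0.001, 0.001) on the precision exp(val)
                lp += float(priors.log_gamma_prior_logkappa(val))
        return lp

    # ------------------------------------------------------------------ #
    def _eta(self, x: np.ndarray) -> np.ndarray:
        eta = self.D @ x[: self.k] + self.offset
        if self.has_u:
            eta = eta + x[self.k :]
        return np.clip(eta, -40.0, 40.0)

    def _penalised_loglik(self, x, Q_dd, Q_u):
        eta = self._eta(x)
        mu = np.exp(eta)
        ll = float(np.sum(self.train_mask * (self.y * eta - mu)))
        d = x[: self.k]
        pen = float(d @ Q_dd @ d)
        if self.has_u:
            u = x[self.k :]
            pen += float(u @ Q_u @ u)
        return ll - 0.5 * pen, mu

    def _hessian(self, mu, Q_dd, Q_u) -> np.ndarray:
        w = mu * self.train_mask
        Dw = self.D * w[:, None]
        H = np.empty((self.n_latent, self.n_latent))
        H[: self.k, : self.k] = self.D.T @ Dw + Q_dd
        if self.has_u:
            H[: self.k, self.k :] = Dw.T
            H[self.k :, : self.k] = Dw
            H[self.k :, self.k :] = Q_u
            H[self.k + np.arange(self.T), self.k + np.arange(self.T)] += w
        return H

    def _newton_mode(self, Q_dd, Q_u, x0):
        cfg = self.config
        x = x0.copy()
        f, mu = self._penalised_loglik(x, Q_dd, Q_u)
        for _ in range(cfg.max_newton_iter):
            r = self.train_mask * (self.y - mu)
            g = np.empty(self.n_latent)
            g[: self.k] = self.D.T @ r - Q_dd @ x[: self.k]
            if self.has_u:
                g[self.k :] = r - Q_u @ x[self.k :]
            H = self._hessian(mu, Q_dd, Q_u)
            try:
                chol = cho_factor(H, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                chol = cho_factor(
                    H + 1e-8 * np.eye(self.n_latent), lower=True, check_finite=False
                )
            step = cho_solve(chol, g, check_finite=False)
            t = 1.0
            for _ in range(30):
                f_new, mu_new = self._penalised_loglik(x + t * step, Q_dd, Q_u)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            x = x + t * step
            improved = f_new - f
            f, mu = f_new, mu_new
            if abs(improved) < cfg.newton_tol * (abs(f) + 1.0):
                break
        H = self._hessian(mu, Q_dd, Q_u)
        chol = cho_factor(H, lower=True, check_finite=False)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        return x, f, chol, logdet_H

    def _neg_log_posterior(self, h: np.ndarray) -> float:
        Q_dd, Q_u, logdet_Q = self._prior_blocks(h)
        x, f, _, logdet_H = self._newton_mode(Q_dd, Q_u, self._x_warm)
        self._x_warm = x
        val = f + 0.5 * logdet_Q - 0.5 * logdet_H + self._hyper_log_prior(h)
        return -val

    # ------------------------------------------------------------------ #
    def fit(self) -> "MonthlyDeathResults":
        cfg = self.config
        x0 = np.zeros(self.n_latent)
        ytr = self.y[self.train_mask]
        ptr = self.population[self.train_mask]
        x0[self.slices["alpha0"]] = np.log(max(ytr.sum(), 0.5) / ptr.sum())
        self._x_warm = x0

        converged = True
        if self._hyper_names:
            h0 = self._default_hyper_init()
            b = cfg.hyper_bound
            # pacf transforms bounded to keep the AR comfortably stationary
            bounds = [
                (-5.0, 5.0) if name.startswith("ar_kappa2") else (-b, b)
                for name in self._hyper_names
            ]
            h0 = np.clip(h0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
            res = optimize.minimize(
                self._neg_log_posterior,
                h0,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": cfg.max_outer_iter,
                    "ftol": cfg.outer_ftol,
                    "eps": cfg.fd_eps,
                },
            )
            h_opt = res.x
            if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
                converged = False
                h_opt = h0
        else:
            h_opt = np.array([])

        Q_dd, Q_u, logdet_Q = self._prior_blocks(h_opt)
        x, f, chol, logdet_H = self._newton_mode(Q_dd, Q_u, self._x_warm)
        if not np.all(np.isfinite(x)):
            converged = False
        log_marginal = f + 0.5 * logdet_Q - 0.5 * logdet_H
        return MonthlyDeathResults(
            model=self,
            latent_mean=x,
            chol=chol,
            hyper=dict(zip(self._hyper_names, h_opt)),
            log_marginal=float(log_marginal),
            converged=bool(converged),
        )


class MonthlyDeathResults:
    """Laplace-approximate posterior for one county x one ensemble spec."""

    def __init__(self, model, latent_mean, chol, hyper, log_marginal, converged):
        self.model = model
        self.spec = model.spec
        self.latent_mean = latent_mean
        self._chol = chol
        self.hyper = hyper
        self.log_marginal = log_marginal
        self.converged = converged

    # -- parameter views ------------------------------------------------ #
    @property
    def params(self) -> dict:
        m = self.model
        x = self.latent_mean
        out: dict = {"alpha0": float(x[m.slices["alpha0"]][0])}
        if "beta" in m.slices:
            out["beta"] = float(x[m.slices["beta"]][0]) / m.config.time_scale
        if "gamma" in m.slices:
            out["gamma"] = float(x[m.slices["gamma"]][0])
        for kname in ("theta", "omega", "nu"):
            if kname in m.slices:
                vals = m._Z12 @ x[m.slices[kname]]
                out[kname] = vals / m.config.time_scale if kname == "omega" else vals
        if m.has_u:
            out["u"] = x[m.k :]  # AR state + overdispersion on training months
            kappa2 = np.array(
                [self.hyper[f"ar_kappa2_{j}"] for j in range(1, self.spec.ar_order + 1)]
            )
            pacf = priors.kappa_to_pacf(kappa2)
            out["ar_pacf"] = pacf
            out["phi"] = priors.pacf_to_ar(pacf)
            out["sigma_zeta_marginal"] = float(np.exp(-0.5 * self.hyper["ar_kappa1"]))
        if "log_tau_eps" in self.hyper:
            out["sigma_eps"] = float(np.exp(-0.5 * self.hyper["log_tau_eps"]))
        return out

    def latent_sd(self, name: str) -> np.ndarray:
        """Posterior standard deviations for a named latent block."""
        m = self.model
        s = m.slices[name]
        sds = []
        for i in range(s.start, s.stop):
            e = np.zeros(m.n_latent)
            e[i] = 1.0
            sds.append(np.sqrt(cho_solve(self._chol, e, check_finite=False)[i]))
        return np.array(sds)

    def fixed_effect_interval(self, name: str, level: float = 0.95):
        """(mean, low, high): equal-tailed Gaussian credible interval."""
        from scipy.stats import norm

        m = self.model
        mean = float(self.latent_mean[m.slices[name]][0])
        sd = float(self.latent_sd(name)[0])
        z = norm.ppf(0.5 + level / 2.0)
        scale = m.config.time_scale if name == "beta" else 1.0
        return mean / scale, (mean - z * sd) / scale, (mean + z * sd) / scale

    # -- sampling -------------------------------------------------------- #
    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draws (n x n_latent) from the Gaussian posterior approximation."""
        L, lower = self._chol
        z = rng.standard_normal((self.model.n_latent, n))
        dev = solve_triangular(L, z, trans="T", lower=lower, check_finite=False)
        return self.latent_mean[None, :] + dev.T

    def predict_counterfactual(
        self, indices, n_draws: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Posterior-predictive death counts at held-out month indices.

        Returns an (len(indices) x n_draws) integer array. Each draw uses
        one joint latent draw, the observed covariates and population offset
        at the month, and a freshly drawn overdispersion term. Valid for
        months excluded from training (counterfactual targets, validation
        holdouts), where the latent residual is the propagated AR state.
        """
        m = self.model
        idx = np.asarray(indices, dtype=int)
        xs = self.sample_latent(n_draws, rng)
        eta = xs[:, : m.k] @ m.D[idx].T + m.offset[idx][None, :]
        if m.has_u:
            eta = eta + xs[:, m.k :][:, idx]
        if "log_tau_eps" in self.hyper:
            sigma_eps = np.exp(-0.5 * self.hyper["log_tau_eps"])
            eta = eta + rng.normal(0.0, sigma_eps, size=eta.shape)
        eta = np.clip(eta, -40.0, 40.0)
        return rng.poisson(np.exp(eta)).T.astype(np.int64)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{self.spec.label}  county={self.model.county_id}",
            f"  training months: {self.model.n_train}/{self.model.T}",
            f"  log marginal likelihood: {self.log_marginal:.2f}",
            f"  alpha0: {p['alpha0']:.4f}",
        ]
        if "beta" in p:
            lines.append(f"  beta (per month): {p['beta']:.3e}")
        if "gamma" in p:
            lines.append(f"  gamma (per degree): {p['gamma']:.4f}")
        if "phi" in p:
            lines.append(f"  AR coefficients: {np.round(p['phi'], 3)}")
        if "sigma_eps" in p:
            lines.append(f"  sigma_eps: {p['sigma_eps']:.4f}")
        lines.append(f"  converged: {self.converged}")
        return "\n".join(lines)


def model_from_panel(
    panel: pd.DataFrame,
    spec: ModelSpec,
    county_id,
    target_mask=None,
    extra_holdout=None,
    config: FitConfig | None = None,
) -> MonthlyDeathModel:
    """Build a county model from panel rows.

    target_mask marks counterfactual target months; extra_holdout marks
    additional months (validation windows) to withhold from training.
    """
    sub = panel[panel["county_id"] == county_id].sort_values("time_index")
    if len(sub) == 0:
        raise ValueError(f"county {county_id} not in panel")
    train = np.ones(len(sub), dtype=bool)
    if target_mask is not None:
        train &= ~np.asarray(target_mask, dtype=bool)
    if extra_holdout is not None:
        train &= ~np.asarray(extra_holdout, dtype=bool)
    return MonthlyDeathModel(
        deaths=sub["deaths"].to_numpy(),
        month=sub["month"].to_numpy(),
        time_index=sub["time_index"].to_numpy(),
        population=sub["population"].to_numpy(),
        anomaly=sub["anomaly"].to_numpy(),
        spec=spec,
        train_mask=train,
        config=config,
        county_id=county_id,
    )
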