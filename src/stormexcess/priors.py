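"""Gaussian prior structures shared by the simulator and the count models.

The monthly count models combine several latent Gaussian components:

* a seasonal month effect whose sums over every 12 consecutive terms are
  independent zero-mean Gaussians (an intrinsic seasonal structure),
* a circular first-order random walk over the 12 calendar months for the
  month-specific temperature slopes,
* a stationary autoregressive series over the monthly time index,
  parameterised through partial autocorrelations so that stationarity is
  automatic, and
* i.i.d. overdispersion terms.

Both the simulator and the fitter go through the functions here, so the
generative model and the fitted model cannot drift apart.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz
from statsmodels.tsa.arima_process import arma_acovf

__all__ = [
    "pacf_to_ar",
    "ar_to_pacf",
    "pacf_to_kappa",
    "kappa_to_pacf",
    "ar1_to_hyper",
    "hyper_to_ar1",
    "ar_innovation_variance",
    "ar_precision",
    "sum_to_zero_basis",
    "circular_rw1_structure",
    "sample_seasonal_path",
    "sample_circular_rw1",
    "log_gamma_prior_logkappa",
]


def pacf_to_ar(pacf: np.ndarray) -> np.ndarray:
    """Map partial autocorrelations to AR coefficients (Levinson-Durbin).

    Every vector with entries in (-1, 1) yields a stationary AR model,
    which is why the models are parameterised on this scale.
    """
    r = np.asarray(pacf, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("pacf must be a non-empty 1-d array")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("partial autocorrelations must lie strictly in (-1, 1)")
    phi = np.array([r[0]])
    for k in range(1, r.size):
        prev = phi
        phi = np.empty(k + 1)
        phi[k] = r[k]
        phi[:k] = prev - r[k] * prev[::-1]
    return phi


def ar_to_pacf(phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pacf_to_ar` (reverse Levinson-Durbin recursion)."""
    phi = np.asarray(phi, dtype=float)
    p = phi.size
    r = np.empty(p)
    work = phi.copy()
    for k in range(p - 1, -1, -1):
        r[k] = work[k]
        if abs(r[k]) >= 1.0:
            raise ValueError("AR coefficients do not correspond to a stationary model")
        if k > 0:
            work = (work[:k] + r[k] * work[:k][::-1]) / (1.0 - r[k] ** 2)
    return r


def pacf_to_kappa(r):
    """Fisher-style transform log((1+r)/(1-r)) used for pacf hyperpriors."""
    r = np.asarray(r, dtype=float)
    return np.log1p(r) - np.log1p(-r)


def kappa_to_pacf(kappa):
    kappa = np.asarray(kappa, dtype=float)
    return np.tanh(kappa / 2.0)


def ar1_to_hyper(phi: float, sigma2_innov: float) -> tuple[float, float]:
    """(phi, innovation variance) -> (kappa1, kappa2).

    kappa1 = log[(1 - phi^2)/sigma2] is the log marginal precision of the
    stationary series; kappa2 = log[(1 + phi)/(1 - phi)].
    """
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must lie in (-1, 1)")
    if sigma2_innov <= 0:
        raise ValueError("innovation variance must be positive")
    kappa1 = np.log((1.0 - phi**2) / sigma2_innov)
    kappa2 = float(pacf_to_kappa(phi))
    return float(kappa1), kappa2


def hyper_to_ar1(kappa1: float, kappa2: float) -> tuple[float, float]:
    phi = float(kappa_to_pacf(kappa2))
    sigma2 = (1.0 - phi**2) / np.exp(kappa1)
    return phi, float(sigma2)


def ar_innovation_variance(pacf: np.ndarray, marginal_var: float) -> float:
    """Innovation variance of a stationary AR with given marginal variance."""
    r = np.asarray(pacf, dtype=float)
    return float(marginal_var * np.prod(1.0 - r**2))


def _stationary_acovf(pacf: np.ndarray, marginal_var: float, nlags: int) -> np.ndarray:
    phi = pacf_to_ar(pacf)
    s2 = ar_innovation_variance(pacf, marginal_var)
    return arma_acovf(np.r_[1.0, -phi], np.array([1.0]), nobs=nlags, sigma2=s2)


def ar_precision(
    pacf: np.ndarray, marginal_var: float, n: int
) -> tuple[np.ndarray, float]:
    """Exact precision matrix and its log-determinant for n steps of a
    stationary AR(p) with the given partial autocorrelations and marginal
    variance.

    Built from the conditional factorisation: the first p values carry the
    stationary density, later values the innovation densities; bandwidth p.
    """
    r = np.asarray(pacf, dtype=float)
    p = r.size
    if n <= p:
        raise ValueError(f"series length {n} must exceed AR order {p}")
    phi = pacf_to_ar(r)
    s2 = ar_innovation_variance(r, marginal_var)
    acovf = _stationary_acovf(r, marginal_var, p)
    sigma_p = toeplitz(acovf)
    sign, logdet_sigma_p = np.linalg.slogdet(sigma_p)
    if sign <= 0:
        raise ValueError("stationary covariance is not positive definite")
    Q = np.zeros((n, n))
    Q[:p, :p] = np.linalg.inv(sigma_p)
    # innovation rows: zeta_t - sum_j phi_j zeta_{t-j}
    B = np.zeros((n - p, n))
    rows = np.arange(n - p)
    B[rows, rows + p] = 1.0
    for j in range(1, p + 1):
        B[rows, rows + p - j] = -phi[j - 1]
    Q += B.T @ B / s2
    logdet = -(n - p) * np.log(s2) - logdet_sigma_p
    return Q, float(logdet)


def sum_to_zero_basis(k: int) -> np.ndarray:
    """Orthonormal basis (k x (k-1)) of the sum-to-zero subspace of R^k."""
    # Householder reflection sending 1/sqrt(k) to e_1; remaining columns span
    # the orthogonal complement of the ones vector.
    v = np.full(k, 1.0 / np.sqrt(k))
    v[0] -= 1.0
    v /= np.linalg.norm(v)
    H = np.eye(k) - 2.0 * np.outer(v, v)
    return H[:, 1:]


def circular_rw1_structure(k: int = 12) -> np.ndarray:
    """Unit-scale intrinsic precision of a circular RW1 with k terms.

    Adjacent months are tied together, with month k adjacent to month 1, so
    effects vary smoothly around the calendar year.
    """
    R = 2.0 * np.eye(k)
    idx = np.arange(k)
    R[idx, (idx + 1) % k] = -1.0
    R[idx, (idx - 1) % k] = -1.0
    return R


def sample_seasonal_path(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a length-n path from the intrinsic seasonal (period 12) prior.

    Constructed so that the sum of every 12 consecutive terms is an
    independent N(0, sigma^2) variate: the first 11 terms are fixed at zero
    and each subsequent term closes its 12-window to a fresh Gaussian sum.
    """
    if n < 12:
        raise ValueError("need at least 12 terms for a period-12 seasonal path")
    theta = np.zeros(n)
    innov = rng.normal(0.0, sigma, size=n - 11)
    for t in range(11, n):
        theta[t] = innov[t - 11] - theta[t - 11 : t].sum()
    return theta


def sample_circular_rw1(
    sigma: float, rng: np.random.Generator, k: int = 12, size: int = 1
) -> np.ndarray:
    """Sample sum-to-zero circular RW1 vectors with increment scale sigma."""
    Z = sum_to_zero_basis(k)
    Qz = Z.T @ circular_rw1_structure(k) @ Z / sigma**2
    cov = np.linalg.inv(Qz)
    L = np.linalg.cholesky(cov)
    draws = rng.standard_normal((size, k - 1)) @ L.T @ Z.T
    return draws[0] if size == 1 else draws


def log_gamma_prior_logkappa(kappa, a: float = 0.001, b: float = 0.001):
    """Log-density (up to a constant) of log-precision kappa when the
    precision exp(kappa) has a Gamma(a, b) prior."""
    kappa = np.asarray(kappa, dtype=float)
    return a * kappa - b * np.exp(kappa)
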