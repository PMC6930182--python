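"""Stationary AR(1) longitudinal covariance and its closed-form Gaussian log-density.

Functional mapping needs the multivariate-normal density of a length-T
residual vector with covariance Sigma(s, t) = sigma2 * rho^|s-t| evaluated
tens of thousands of times per scan.  For AR(1) both the determinant and
the inverse are available in closed form,

    |Sigma|      = sigma2^T (1 - rho^2)^(T-1)
    Sigma^{-1}   = tridiagonal / (sigma2 (1 - rho^2))

so the log-density costs O(T) instead of an O(T^3) solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AR1Params", "ar1_matrix", "ar1_logpdf", "ar1_quadform", "profile_sigma2"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class AR1Params:
    """Lag-1 correlation and time-constant variance of a stationary AR(1) process."""

    rho: float
    sigma2: float

    def __post_init__(self):
        if not (abs(self.rho) < 1.0):
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not (self.sigma2 > 0.0):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")


def ar1_matrix(p: AR1Params, T: int) -> np.ndarray:
    """Dense T x T covariance with entries sigma2 * rho^|s-t|."""
    if T < 1:
        raise ValueError("T must be >= 1")
    idx = np.arange(T)
    return p.sigma2 * p.rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_quadform(residuals: np.ndarray, rho: float) -> float:
    """Quadratic form r' (Sigma/sigma2)^{-1} r for the AR(1) correlation matrix.

    ``residuals`` may be 1-D (one subject) or 2-D (subjects x occasions);
    rows are summed.  Uses the tridiagonal inverse: for T >= 2

        r' C^{-1} r = [r_1^2 + r_T^2 + (1+rho^2) sum_{2..T-1} r_t^2
                       - 2 rho sum_{1..T-1} r_t r_{t+1}] / (1 - rho^2)
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    T = r.shape[1]
    if T == 1:
        return float(np.sum(r * r))
    ss = np.sum(r * r)
    ss_inner = np.sum(r[:, 1:-1] * r[:, 1:-1])
    cross = np.sum(r[:, :-1] * r[:, 1:])
    return float((ss + rho * rho * ss_inner - 2.0 * rho * cross) / (1.0 - rho * rho))


def ar1_logpdf(residuals: np.ndarray, p: AR1Params) -> float:
    """Log-density of N(0, ar1_matrix(p, T)) at the residual vector(s).

    2-D input is treated as independent subjects sharing (rho, sigma2); the
    summed log-density is returned.  Result is always finite for valid
    parameters; a non-finite value raises ``FloatingPointError``.
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, T = r.shape
    logdet1 = T * math.log(p.sigma2) + (T - 1) * math.log1p(-p.rho * p.rho)
    q = ar1_quadform(r, p.rho) / p.sigma2
    out = -0.5 * (n * T * _LOG2PI + n * logdet1 + q)
    if not math.isfinite(out):
        raise FloatingPointError("AR(1) log-density is not finite")
    return out


def profile_sigma2(residuals: np.ndarray, rho: float, min_sigma2: float = 1e-12) -> float:
    """Analytic MLE of sigma2 given rho: the quadratic form per observation."""
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    n, T = r.shape
    return max(ar1_quadform(r, rho) / (n * T), min_sigma2)
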