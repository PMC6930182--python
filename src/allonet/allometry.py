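"""Bidirectional height-diameter allometry equations and their least-squares fitting.

Stem height H and stem diameter D are linked by a saturating allometric
equation that can be read in either scaling direction:

    H(t) = H0 + exp(a + d / (b + D(t)))            (height from diameter)
    D(t) = d / (a - ln(H(t) - H0)) - b             (diameter from height)

The two forms are exact algebraic inverses of each other under the sign
convention ``d_HfromD = -d_DfromH`` (with ``a`` and ``b`` shared).  ``H0``
is the stem height at the initial time point; ``a`` governs the late-stage
asymptote (H -> H0 + e^a as the predictor grows), ``b`` shifts the
early-stage behaviour and ``d`` is a relative rate that sets how fast the
curve spreads along the predictor axis.  ``d < 0`` gives curves that
increase with the predictor in the height-from-diameter direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "Direction",
    "AllometryParams",
    "AllometryDomainError",
    "predict_h_from_d",
    "predict_d_from_h",
    "predict",
    "fit_allometry",
    "compare_models_aic",
]

_PENALTY = 1e12


class Direction(str, Enum):
    """Scaling direction of the allometric equation."""

    H_FROM_D = "H_FROM_D"  # height as a function of diameter (piQTL side)
    D_FROM_H = "D_FROM_H"  # diameter as a function of height (miQTL side)


class AllometryDomainError(ValueError):
    """Predictor value outside the domain of the allometry equation."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class AllometryParams:
    """One (a, b, d) coefficient triple plus baseline for one scaling direction."""

    direction: Direction
    h0: float
    a: float
    b: float
    d: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.a, self.b, self.d], dtype=float)

    def inverse(self) -> "AllometryParams":
        """Matched parameters of the opposite scaling direction (d flips sign)."""
        other = (
            Direction.D_FROM_H
            if self.direction == Direction.H_FROM_D
            else Direction.H_FROM_D
        )
        return replace(self, direction=other, d=-self.d)


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        idx = int(np.flatnonzero(~np.isfinite(x))[0])
        raise AllometryDomainError(f"non-finite {name} at index {idx}", idx)


def predict_h_from_d(params: AllometryParams, d_values: Sequence[float]) -> np.ndarray:
    """Evaluate H = h0 + exp(a + d/(b + D)) at the given diameters.

    Raises :class:`AllometryDomainError` when ``b + D <= 0`` for any input.
    """
    if params.direction != Direction.H_FROM_D:
        raise ValueError("params.direction must be H_FROM_D")
    d_arr = np.asarray(d_values, dtype=float)
    _check_finite(d_arr, "diameter")
    denom = params.b + d_arr
    if np.any(denom <= 0):
        idx = int(np.flatnonzero(denom <= 0)[0])
        raise AllometryDomainError(
            f"b + D = {denom.flat[idx]:g} <= 0 at index {idx}", idx
        )
    return params.h0 + np.exp(params.a + params.d / denom)


def predict_d_from_h(params: AllometryParams, h_values: Sequence[float]) -> np.ndarray:
    """Evaluate D = d/(a - ln(H - h0)) - b at the given heights.

    Raises :class:`AllometryDomainError` when ``H <= h0``, when the
    denominator ``a - ln(H - h0)`` is non-positive, or when the predicted
    diameter is negative (out of the physical domain).
    """
    if params.direction != Direction.D_FROM_H:
        raise ValueError("params.direction must be D_FROM_H")
    h_arr = np.asarray(h_values, dtype=float)
    _check_finite(h_arr, "height")
    excess = h_arr - params.h0
    if np.any(excess <= 0):
        idx = int(np.flatnonzero(excess <= 0)[0])
        raise AllometryDomainError(f"H <= h0 at index {idx}", idx)
    denom = params.a - np.log(excess)
    if np.any(denom <= 0):
        idx = int(np.flatnonzero(denom <= 0)[0])
        raise AllometryDomainError(
            f"a - ln(H - h0) = {denom.flat[idx]:g} <= 0 at index {idx}", idx
        )
    out = params.d / denom - params.b
    if np.any(out < 0):
        idx = int(np.flatnonzero(out < 0)[0])
        raise AllometryDomainError(
            f"predicted diameter {out.flat[idx]:g} < 0 at index {idx}", idx
        )
    return out


def predict(params: AllometryParams, x: Sequence[float]) -> np.ndarray:
    """Dispatch on ``params.direction``."""
    if params.direction == Direction.H_FROM_D:
        return predict_h_from_d(params, x)
    return predict_d_from_h(params, x)


# ---------------------------------------------------------------------------
# penalised mean evaluation used inside optimisers: instead of raising,
# out-of-domain parameter proposals get a large finite objective so the
# simplex can walk back into the feasible region.


def _mean_h_from_d(theta: np.ndarray, h0, x: np.ndarray):
    a, b, d = theta
    denom = b + x
    if denom.min() <= 1e-12:
        return None
    z = a + d / denom
    if z.max() > 500.0:
        return None
    return h0 + np.exp(z)


def _mean_d_from_h(theta: np.ndarray, h0, x: np.ndarray):
    a, b, d = theta
    excess = x - h0
    if excess.min() <= 0:
        return None
    denom = a - np.log(excess)
    if denom.min() <= 1e-12:
        return None
    return d / denom - b


def eval_mean(theta: np.ndarray, h0, x: np.ndarray, direction: Direction):
    """Mean curve for parameter triple ``theta = (a, b, d)``; ``None`` if out of domain.

    ``h0`` may be a scalar or an array broadcastable against ``x`` (the
    per-individual baseline used by the functional-mapping likelihood).
    """
    if direction == Direction.H_FROM_D:
        return _mean_h_from_d(theta, h0, x)
    return _mean_d_from_h(theta, h0, x)


def _initial_guess(x, y, h0, direction: Direction) -> np.ndarray:
    """Heuristic (a, b, d) start obtained by linearising the equation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if direction == Direction.H_FROM_D:
        # ln(y - h0) = a + d/(b + x): fix b, regress on 1/(b + x)
        b0 = max(1.0, 1e-3 - float(np.min(x)))
        w = np.log(np.maximum(y - h0, 1e-6))
        u = 1.0 / (b0 + x)
        A = np.column_stack([np.ones_like(u), u])
        coef, *_ = np.linalg.lstsq(A, w, rcond=None)
        return np.array([coef[0], b0, coef[1]])
    # y = d/(a - ln(x - h0)) - b: fix a above max ln(x - h0), regress on the
    # reciprocal term
    v = np.log(np.maximum(x - h0, 1e-6))
    a0 = float(np.max(v)) + 0.5
    u = 1.0 / (a0 - v)
    A = np.column_stack([u, -np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.array([a0, coef[1], coef[0]])


@dataclass
class FitResult:
    params: AllometryParams
    rss: float
    converged: bool
    n_starts: int = 1


def fit_allometry(
    x: Sequence[float],
    y: Sequence[float],
    direction: Direction,
    init: AllometryParams | None = None,
    h0: float | None = None,
    fit_h0: bool = False,
    n_starts: int = 5,
    seed: int | None = 0,
    max_iter: int = 2000,
) -> FitResult:
    """Least-squares fit of the allometry equation by multi-start Nelder-Mead.

    Parameters
    ----------
    x, y
        Predictor and response sequences of equal length (>= 4).
    direction
        Which equation to fit; ``x`` must lie in its domain.
    init
        Optional warm start.  The returned rss never exceeds the rss at
        ``init``.
    h0
        Fixed baseline.  Defaults to ``init.h0`` if given, otherwise to
        ``min(y) - 1`` (H_FROM_D) / 0 (D_FROM_H predictor baseline).
    fit_h0
        Treat the baseline as a fourth free parameter (the mean-curve use
        case where no per-individual baseline exists).
    n_starts
        Number of jittered simplex starts (first start is unjittered).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    k_free = 4 if fit_h0 else 3
    if len(x) < k_free + 1:
        raise ValueError(f"need at least {k_free + 1} observations")
    _check_finite(x, "x")
    _check_finite(y, "y")

    if h0 is None:
        if init is not None:
            h0 = init.h0
        elif direction == Direction.H_FROM_D:
            h0 = float(np.min(y)) - 1.0
        else:
            h0 = float(np.min(x)) - 1.0

    rng = np.random.default_rng(seed)

    def objective(theta_full: np.ndarray) -> float:
        if fit_h0:
            theta, h0_cur = theta_full[:3], theta_full[3]
        else:
            theta, h0_cur = theta_full, h0
        mu = eval_mean(theta, h0_cur, x, direction)
        if mu is None:
            return _PENALTY
        r = y - mu
        rss = float(r @ r)
        return rss if math.isfinite(rss) else _PENALTY

    base = _initial_guess(x, y, h0, direction) if init is None else init.as_vector()
    if fit_h0:
        base = np.append(base, h0)

    best_theta, best_rss = None, np.inf
    for s in range(max(1, n_starts)):
        start = base if s == 0 else base * (1 + 0.2 * rng.standard_normal(base.size)) + 0.1 * rng.standard_normal(base.size)
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-12},
        )
        if res.fun < best_rss:
            best_rss, best_theta = float(res.fun), np.asarray(res.x)

    converged = best_rss < _PENALTY
    if fit_h0:
        a, b, d = best_theta[:3]
        h0_out = float(best_theta[3])
    else:
        a, b, d = best_theta
        h0_out = float(h0)
    params = AllometryParams(direction=direction, h0=h0_out, a=float(a), b=float(b), d=float(d))
    if init is not None:
        init_vec = init.as_vector() if not fit_h0 else np.append(init.as_vector(), init.h0)
        if objective(init_vec) < best_rss:  # pragma: no cover - safety net
            params, best_rss = init, float(objective(init_vec))
    return FitResult(params=params, rss=best_rss, converged=converged, n_starts=n_starts)


# ---------------------------------------------------------------------------
# AIC model comparison against simple comparators


def _fit_power(x, y):
    # y = alpha * x^beta, fitted in log-log space then polished
    lx, ly = np.log(x), np.log(np.maximum(y, 1e-12))
    A = np.column_stack([np.ones_like(lx), lx])
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)

    def obj(p):
        alpha, beta = p
        with np.errstate(over="ignore", invalid="ignore"):
            mu = alpha * np.power(x, beta)
        r = y - mu
        rss = float(r @ r)
        return rss if math.isfinite(rss) else _PENALTY

    res = minimize(obj, [math.exp(coef[0]), coef[1]], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return float(res.fun), 2


def _fit_linear(x, y):
    A = np.column_stack([np.ones_like(x), x])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r), 2


def compare_models_aic(
    x: Sequence[float],
    y: Sequence[float],
    direction: Direction = Direction.H_FROM_D,
    candidate_models: Sequence[str] = ("allometry", "power", "linear"),
    seed: int = 0,
):
    """Fit candidate mean-curve models and rank them by AIC.

    AIC = n ln(rss/n) + 2k.  Returns a list of dicts sorted by ascending
    AIC, ties broken by fewer parameters.  A candidate whose fit fails is
    kept with AIC = +inf.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    rows = []
    for model in candidate_models:
        try:
            if model == "allometry":
                fit = fit_allometry(x, y, direction, fit_h0=True, seed=seed)
                rss, k = fit.rss, 4
            elif model == "power":
                rss, k = _fit_power(x, y)
            elif model == "linear":
                rss, k = _fit_linear(x, y)
            else:
                raise ValueError(f"unknown candidate model {model!r}")
            if n <= k:
                raise ValueError("n must exceed the number of parameters")
            aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
        except ValueError:
            raise
        except Exception:
            rss, k, aic = math.inf, 0, math.inf
        rows.append({"model": model, "k": k, "rss": rss, "aic": aic})
    rows.sort(key=lambda r: (r["aic"], r["k"]))
    return rows
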