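"""ODE decomposition of QTL effect curves into independent and regulator-driven parts.

The rate of change of a focal QTL's genetic-effect curve P_k(t) is split
into an independent component and the aggregated influence of the other
QTLs,

    dP_k/dt = U_k(P_k(t)) + sum_{k' != k}  U_kk'(P_k'(t)),

where each U is a nonparametric smoothing function, here a Legendre
polynomial expansion of order ``r`` in its own argument (rescaled to
[-1, 1] over the argument's observed range).  The constant basis term is
carried only by the independent component so the decomposition is
identifiable.

The workflow is two-stage, mirroring sparse dynamical-network inference
practice:

1. *Regulator selection* — regress the numerically differentiated focal
   curve on the basis-expanded candidate curves with a group-sparsity
   principle (one group of ``r`` columns per candidate; the intercept and
   the focal's own basis are unpenalised).  The default backend is greedy
   group-forward selection with full refitting and an extended-BIC stop;
   a proximal-gradient group lasso over a geometric penalty path with BIC
   refitting is available as ``method="lasso"``.
2. *ODE refinement* — for each focal QTL, minimise the squared distance
   between the observed curve and the 4th-order Runge-Kutta solution of
   the ODE, with regulator curves held at their observed (linearly
   interpolated) values.  Because the dependent terms depend only on
   observed regulator curves, each focal QTL is fitted independently.

Edges inherit a sign (time-average of the dependent component), a weight
(mean absolute derivative contribution), and the pairwise labels of the
activation/neutrality/repression classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from numpy.polynomial import legendre
from scipy.interpolate import make_lsq_spline
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .funmap import EffectCurve

__all__ = [
    "ODEComponentParams",
    "NetworkNode",
    "NetworkEdge",
    "QTLNetwork",
    "select_regulators",
    "forward_select",
    "regulator_scores",
    "group_lasso_path",
    "fit_qdode",
    "decompose_effects",
    "infer_network",
    "classify_interactions",
    "detect_hubs",
    "export_network",
    "read_network",
]

INTERACTION_LABELS = {
    (1, 1): "symmetric positive epistasis",
    (0, 0): "symbiosis",
    (-1, -1): "negative epistasis",
    (1, 0): "directional positive epistasis",
    (0, 1): "directional positive epistasis",
    (0, -1): "directional negative epistasis",
    (-1, 0): "directional negative epistasis",
    (1, -1): "altruistic or repressive epistasis",
    (-1, 1): "altruistic or repressive epistasis",
}


# ---------------------------------------------------------------------------
# basis utilities


def _range_of(values: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-8:
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def _scale(values: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    lo, hi = rng
    return 2.0 * (values - lo) / (hi - lo) - 1.0


def _legendre_cols(values: np.ndarray, rng: tuple[float, float], r: int,
                   include_const: bool) -> np.ndarray:
    """Columns L_1..L_r (optionally L_0..L_r) of the scaled argument."""
    V = legendre.legvander(_scale(values, rng), r)
    return V if include_const else V[:, 1:]


def _diff_curve(t: np.ndarray, y: np.ndarray, smooth: bool) -> tuple[np.ndarray, np.ndarray]:
    """(optionally smoothed curve, its derivative on the grid).

    With ``smooth`` a fixed-complexity cubic least-squares spline (four
    interior knots, effective df 8) is fitted and differentiated
    analytically.  The complexity is held fixed rather than tuned by GCV:
    the residuals of effect curves are serially correlated, which makes
    GCV chase noise, and a fixed df means denser sampling buys real
    averaging.  Without ``smooth``, central differences (one-sided at the
    ends) are used.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if smooth and len(y) >= 10:
        n_int = min(4, len(y) - 6)
        knots = np.linspace(t[0], t[-1], n_int + 2)[1:-1]
        tk = np.concatenate([[t[0]] * 4, knots, [t[-1]] * 4])
        spl = make_lsq_spline(t, y, tk, k=3)
        return spl(t), spl.derivative()(t)
    if smooth and len(y) >= 7:
        ys = savgol_filter(y, window_length=min(7, len(y)), polyorder=3)
        return ys, np.gradient(ys, t)
    return y, np.gradient(y, t)


# ---------------------------------------------------------------------------
# group lasso (FISTA) for regulator selection


def _fista_group_lasso(X: np.ndarray, y: np.ndarray, groups: list[np.ndarray],
                       weights: np.ndarray, lam: float, beta0: np.ndarray | None = None,
                       max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Minimise 0.5||y - X b||^2 + lam * sum_g w_g ||b_g||_2.

    Columns not covered by ``groups`` are unpenalised.  Plain FISTA with a
    fixed step from the spectral norm of X.
    """
    n, p = X.shape
    L = float(np.linalg.norm(X, 2)) ** 2
    if L == 0:
        return np.zeros(p)
    step = 1.0 / L
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    z = beta.copy()
    tk = 1.0
    XtX = X.T @ X
    Xty = X.T @ y
    for _ in range(max_iter):
        grad = XtX @ z - Xty
        nxt = z - step * grad
        for g, w in zip(groups, weights):
            v = nxt[g]
            nrm = math.sqrt(float(v @ v))
            thr = lam * w * step
            nxt[g] = 0.0 if nrm <= thr else v * (1.0 - thr / nrm)
        tnext = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * tk * tk))
        z = nxt + ((tk - 1.0) / tnext) * (nxt - beta)
        delta = float(np.max(np.abs(nxt - beta)))
        beta, tk = nxt, tnext
        if delta < tol:
            break
    return beta


@dataclass
class _SelectionProblem:
    X: np.ndarray           # full design: unpenalised cols then candidate groups
    y: np.ndarray           # differentiated focal curve
    groups: list[np.ndarray]
    weights: np.ndarray
    candidate_ids: list[str]
    n_unpen: int


def _build_selection_problem(focal: EffectCurve, candidates: Sequence[EffectCurve],
                             r: int, smooth: bool) -> _SelectionProblem:
    t = np.asarray(focal.grid, dtype=float)
    for c in candidates:
        if len(c.grid) != len(t) or not np.allclose(np.asarray(c.grid, float), t):
            raise ValueError(f"candidate {c.qtl_id}: grid mismatch with focal {focal.qtl_id}")
        if c.qtl_id == focal.qtl_id:
            raise ValueError("focal curve must not appear among the candidates")
    if len(t) < 5:
        raise ValueError("need at least 5 shared occasions")
    y_s, dy = _diff_curve(t, np.asarray(focal.values, float), smooth)
    cols = [np.ones((len(t), 1)),
            _legendre_cols(y_s, _range_of(y_s), r, include_const=False)]
    n_unpen = 1 + r
    groups, ids = [], []
    start = n_unpen
    for c in candidates:
        v, _ = _diff_curve(t, np.asarray(c.values, float), smooth)
        cols.append(_legendre_cols(v, _range_of(v), r, include_const=False))
        groups.append(np.arange(start, start + r))
        ids.append(c.qtl_id)
        start += r
    X = np.hstack(cols)
    # centre and unit-norm penalised columns: the penalty becomes
    # scale-free and constant candidate curves (basis columns collinear
    # with the intercept) drop out instead of being spuriously selected
    for g in groups:
        X[:, g] -= X[:, g].mean(axis=0)
        nrm = np.linalg.norm(X[:, g], axis=0)
        nrm[nrm < 1e-12] = 1.0
        X[:, g] /= nrm
    weights = np.full(len(groups), math.sqrt(r))
    return _SelectionProblem(X, dy, groups, weights, ids, n_unpen)


def _lambda_max(prob: _SelectionProblem) -> float:
    # residual after projecting out the unpenalised columns
    U = prob.X[:, : prob.n_unpen]
    coef, *_ = np.linalg.lstsq(U, prob.y, rcond=None)
    res = prob.y - U @ coef
    vals = [np.linalg.norm(prob.X[:, g].T @ res) / w for g, w in zip(prob.groups, prob.weights)]
    return max(max(vals), 1e-12)


def group_lasso_path(focal: EffectCurve, candidates: Sequence[EffectCurve],
                     r: int = 4, n_lambda: int = 20, lambda_min_ratio: float = 1e-3,
                     smooth: bool = True):
    """Group-lasso solution path of candidate group norms.

    Returns ``(lambdas, norms)`` with ``lambdas`` descending and ``norms``
    of shape (n_lambda, n_candidates): the L2 norm of each candidate's
    coefficient group at each penalty.
    """
    prob = _build_selection_problem(focal, candidates, r, smooth)
    lmax = _lambda_max(prob)
    lambdas = lmax * np.exp(np.linspace(0.0, math.log(lambda_min_ratio), n_lambda))
    norms = np.zeros((len(lambdas), len(prob.candidate_ids)))
    beta = None
    for i, lam in enumerate(lambdas):
        beta = _fista_group_lasso(prob.X, prob.y, prob.groups, prob.weights, lam, beta0=beta)
        for j, g in enumerate(prob.groups):
            norms[i, j] = float(np.linalg.norm(beta[g]))
    return lambdas, norms, prob


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return max(float(r @ r), 1e-12)


def forward_select(focal: EffectCurve, candidates: Sequence[EffectCurve],
                   r: int = 2, smooth: bool = True, max_regulators: int = 6,
                   ebic_gamma: float = 1.0):
    """Greedy group-forward selection of regulators with an EBIC stopping rule.

    Starting from the unpenalised self model, the candidate group giving
    the largest residual-sum-of-squares drop is added at each step (with
    full refitting, so a regulator whose relevance only appears after a
    partner is included is still found).  The kept model size minimises
    the extended BIC  n ln(rss/n) + k ln n + 2 gamma ln C(p, k_groups).

    Returns ``(selected ids, scores)`` where scores maps every candidate
    to a continuous evidence value: the log rss gain at its entry step
    (never-entered candidates get their would-be terminal gain, capped
    below the weakest entrant), suitable for ROC threshold sweeps.
    """
    prob = _build_selection_problem(focal, candidates, r, smooth)
    n, p = len(prob.y), len(prob.candidate_ids)
    if np.allclose(prob.y, 0.0):
        return [], {cid: 0.0 for cid in prob.candidate_ids}
    active = list(range(prob.n_unpen))
    rss = _rss(prob.X[:, active], prob.y)
    rss_path = [rss]
    remaining = set(range(p))
    order: list[int] = []
    gains: dict[int, float] = {}
    kmax = min(max_regulators, p, max(0, (n - prob.n_unpen) // r - 1))
    rss_floor = 1e-4 * max(float(prob.y @ prob.y), 1e-8)
    for _ in range(kmax):
        if rss < rss_floor:  # > 99.99% of the derivative variance explained:
            break            # anything further fits discretisation error
        best = None
        for j in remaining:
            rj = _rss(prob.X[:, active + list(prob.groups[j])], prob.y)
            if best is None or rj < best[1]:
                best = (j, rj)
        j, rj = best
        gains[j] = math.log(rss / rj)
        order.append(j)
        active += list(prob.groups[j])
        remaining.discard(j)
        rss = rj
        rss_path.append(rss)
    floor = min((gains[o] for o in order), default=1.0)
    for j in remaining:
        rj = _rss(prob.X[:, active + list(prob.groups[j])], prob.y)
        gains[j] = min(math.log(rss / rj), 0.99 * floor)
    best_k, best_val = 0, n * math.log(rss_path[0] / n) + prob.n_unpen * math.log(n)
    for k in range(1, len(rss_path)):
        kcols = prob.n_unpen + k * r
        val = (n * math.log(rss_path[k] / n) + kcols * math.log(n)
               + 2.0 * ebic_gamma * math.log(math.comb(p, k)))
        if val < best_val:
            best_k, best_val = k, val
    selected = [prob.candidate_ids[j] for j in order[:best_k]]
    scores = {prob.candidate_ids[j]: g for j, g in gains.items()}
    return selected, scores


def select_regulators(focal: EffectCurve, candidates: Sequence[EffectCurve],
                      lam: float | None = None, r: int = 2, n_lambda: int = 20,
                      smooth: bool = True, norm_tol: float = 1e-6,
                      method: str = "forward") -> list[str]:
    """Regulators of the focal QTL chosen by group-sparse regression.

    The default backend is greedy group-forward selection with an EBIC
    stop (:func:`forward_select`).  ``method="lasso"`` uses the group
    lasso path instead: with ``lam`` given, candidates whose group is
    nonzero at that penalty; otherwise the penalty chosen by BIC along
    the path (the active set refitted by OLS at each point), ordered by
    decreasing group norm.  A fixed ``lam`` always routes to the lasso
    backend.
    """
    if method == "forward" and lam is None:
        selected, _ = forward_select(focal, candidates, r=r, smooth=smooth)
        return selected
    if np.allclose(np.gradient(np.asarray(focal.values, float),
                               np.asarray(focal.grid, float)), 0.0):
        return []
    if lam is not None:
        prob = _build_selection_problem(focal, candidates, r, smooth)
        beta = _fista_group_lasso(prob.X, prob.y, prob.groups, prob.weights, lam)
        pairs = [(cid, float(np.linalg.norm(beta[g])))
                 for cid, g in zip(prob.candidate_ids, prob.groups)]
        pairs = [(cid, nrm) for cid, nrm in pairs if nrm > norm_tol]
        return [cid for cid, _ in sorted(pairs, key=lambda p: -p[1])]

    lambdas, norms, prob = group_lasso_path(focal, candidates, r, n_lambda, smooth=smooth)
    n = len(prob.y)
    best = (math.inf, [])
    seen = set()
    for i in range(len(lambdas)):
        support = tuple(j for j in range(norms.shape[1]) if norms[i, j] > norm_tol)
        if support in seen:
            continue
        seen.add(support)
        cols = list(range(prob.n_unpen)) + [c for j in support for c in prob.groups[j]]
        Xs = prob.X[:, cols]
        coef, *_ = np.linalg.lstsq(Xs, prob.y, rcond=None)
        res = prob.y - Xs @ coef
        rss = max(float(res @ res), 1e-12)
        k = len(cols)
        bic = n * math.log(rss / n) + k * math.log(n)
        if bic < best[0]:
            ordered = sorted(support, key=lambda j: -norms[i, j])
            best = (bic, [prob.candidate_ids[j] for j in ordered])
    return best[1]


def regulator_scores(focal: EffectCurve, candidates: Sequence[EffectCurve],
                     r: int = 2, n_lambda: int = 20, smooth: bool = True,
                     norm_tol: float = 1e-6, method: str = "forward") -> dict[str, float]:
    """Continuous evidence score per candidate, used to sweep ROC thresholds.

    With the forward backend: the log rss gain at the candidate's entry
    into the greedy path.  With ``method="lasso"``: the largest penalty
    (normalised by lambda_max) at which the candidate's group first
    becomes active on the group-lasso path (0 if never).
    """
    if method == "forward":
        _, scores = forward_select(focal, candidates, r=r, smooth=smooth)
        return scores
    lambdas, norms, prob = group_lasso_path(focal, candidates, r, n_lambda, smooth=smooth)
    scores = {}
    for j, cid in enumerate(prob.candidate_ids):
        active = np.flatnonzero(norms[:, j] > norm_tol)
        scores[cid] = float(lambdas[active[0]] / lambdas[0]) if active.size else 0.0
    return scores


# ---------------------------------------------------------------------------
# ODE fitting


@dataclass
class ODEComponentParams:
    """Fitted Legendre coefficients of one focal QTL's ODE decomposition."""

    qtl_id: str
    basis_order: int
    phi_self: np.ndarray                 # orders 0..r
    phi_dep: dict[str, np.ndarray]       # per regulator, orders 1..r
    self_range: tuple[float, float]
    dep_ranges: dict[str, tuple[float, float]]
    converged: bool = True
    objective: float = math.nan


class _RK4Problem:
    """Pre-tabulated RK4 stage data for one focal QTL.

    Stage times are fixed, so each regulator's basis matrix at every stage
    is computed once; an objective evaluation only propagates the focal
    state through the self-term expansion.
    """

    def __init__(self, focal: EffectCurve, regulators: list[EffectCurve],
                 r: int, n_sub: int = 4):
        self.r = r
        self.t = np.asarray(focal.grid, dtype=float)
        self.y_obs = np.asarray(focal.values, dtype=float)
        self.self_range = _range_of(self.y_obs)
        self.n_steps = (len(self.t) - 1) * n_sub
        # substep sizes and stage times (t, t+h/2, t+h) per substep
        edges = []
        for i in range(len(self.t) - 1):
            edges.extend(np.linspace(self.t[i], self.t[i + 1], n_sub + 1)[:-1])
        edges.append(self.t[-1])
        self.edges = np.asarray(edges)
        self.h = np.diff(self.edges)
        mid = self.edges[:-1] + self.h / 2.0
        self.stage_times = np.stack([self.edges[:-1], mid, self.edges[1:]], axis=1)
        self.obs_at = np.arange(len(self.t)) * n_sub
        self.reg_ids = [c.qtl_id for c in regulators]
        self.dep_ranges = {}
        self.reg_basis = {}  # id -> (n_steps, 3, r) basis at the three stage times
        for c in regulators:
            vals = np.asarray(c.values, dtype=float)
            rng = _range_of(vals)
            interp = np.interp(self.stage_times, self.t, vals)
            self.dep_ranges[c.qtl_id] = rng
            # anchor the dependent basis at the regulator's initial level:
            # U_kk'(Q'(t1)) = 0 by construction, which resolves the
            # constant-splitting ambiguity between self and dependent terms
            b0 = _legendre_cols(vals[:1], rng, r, include_const=False)
            self.reg_basis[c.qtl_id] = (
                _legendre_cols(interp.ravel(), rng, r, include_const=False) - b0
            ).reshape(self.n_steps, 3, r)
        lo, hi = self.self_range
        self.clip_lo = lo - 5.0 * (hi - lo)
        self.clip_hi = hi + 5.0 * (hi - lo)

    def dep_drive(self, phi_dep: dict[str, np.ndarray]):
        """g(t) at every stage: summed dependent term, shape (n_steps, 3)."""
        g = np.zeros((self.n_steps, 3))
        for rid, phi in phi_dep.items():
            g += self.reg_basis[rid] @ phi
        return g

    def _u_self(self, P: float, phi_self: np.ndarray) -> float:
        u = 2.0 * (P - self.self_range[0]) / (self.self_range[1] - self.self_range[0]) - 1.0
        return float(legendre.legval(u, phi_self))

    def integrate(self, phi_self: np.ndarray, g: np.ndarray,
                  component_tracking: bool = False):
        """RK4 trajectory from y_obs[0]; optionally per-component increments.

        The dependent drive g is a pure function of time, so inside one RK4
        step its stage values are fixed; the step increment splits exactly
        into a self part and per-stage dependent parts, making the
        decomposition additive by construction.
        """
        P = float(self.y_obs[0])
        traj = np.empty(self.n_steps + 1)
        traj[0] = P
        self_inc = np.zeros(self.n_steps) if component_tracking else None
        blew_up = False
        for s in range(self.n_steps):
            h = self.h[s]
            g0, gm, g1 = g[s]
            u1 = self._u_self(P, phi_self)
            k1 = u1 + g0
            u2 = self._u_self(P + 0.5 * h * k1, phi_self)
            k2 = u2 + gm
            u3 = self._u_self(P + 0.5 * h * k2, phi_self)
            k3 = u3 + gm
            u4 = self._u_self(P + h * k3, phi_self)
            k4 = u4 + g1
            P = P + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if not math.isfinite(P) or P < self.clip_lo or P > self.clip_hi:
                blew_up = True
                P = min(max(P if math.isfinite(P) else self.clip_hi, self.clip_lo), self.clip_hi)
            traj[s + 1] = P
            if component_tracking:
                self_inc[s] = h / 6.0 * (u1 + 2 * u2 + 2 * u3 + u4)
        if component_tracking:
            return traj, self_inc, blew_up
        return traj, blew_up


def _gradient_match_init(problem: _RK4Problem, regulators: list[EffectCurve],
                         r: int, smooth: bool, pin_initial_rate: bool = False):
    """Linear least-squares start: regress the differentiated focal curve
    on the basis expansions of itself and its regulators.

    With ``pin_initial_rate`` the total rate at the first occasion is
    constrained to the observed initial derivative.  For curves that take
    off from near an equilibrium, the free regression leaves a small
    intercept error that shifts the fitted onset by many occasions; the
    constrained start avoids that local minimum of the trajectory
    objective.
    """
    t, y = problem.t, problem.y_obs
    y_s, dy = _diff_curve(t, y, smooth)
    cols = [_legendre_cols(y_s, problem.self_range, r, include_const=True)]
    for c in regulators:
        v, _ = _diff_curve(t, np.asarray(c.values, float), smooth)
        rng = problem.dep_ranges[c.qtl_id]
        b0 = _legendre_cols(np.asarray(c.values, float)[:1], rng, r, include_const=False)
        cols.append(_legendre_cols(v, rng, r, include_const=False) - b0)
    X = np.hstack(cols)
    if pin_initial_rate:
        b1 = X[0]
        Xr = X[:, 1:] - np.outer(X[:, 0] / b1[0], b1[1:])
        yr = dy - X[:, 0] * dy[0] / b1[0]
        rest, *_ = np.linalg.lstsq(Xr, yr, rcond=None)
        coef = np.concatenate([[(dy[0] - rest @ b1[1:]) / b1[0]], rest])
    else:
        coef, *_ = np.linalg.lstsq(X, dy, rcond=None)
    phi_self = coef[: r + 1]
    phi_dep = {}
    start = r + 1
    for c in regulators:
        phi_dep[c.qtl_id] = coef[start: start + r]
        start += r
    return phi_self, phi_dep


def fit_qdode(curves: Sequence[EffectCurve],
              regulator_map: dict[str, list[str]],
              basis_order: int = 2,
              n_sub: int = 4,
              smooth: bool = True,
              max_nfev: int = 200) -> dict[str, ODEComponentParams]:
    """Fit the per-focal ODE decomposition by trajectory least squares.

    For each focal QTL listed in ``regulator_map`` the Legendre
    coefficients of its self term and of each regulator term are chosen to
    minimise the squared distance between the observed curve and the RK4
    solution started at the first observation, with regulator curves held
    at their observed interpolated values.  Initialised by gradient
    matching, refined with a trust-region least-squares solver.
    """
    by_id = {c.qtl_id: c for c in curves}
    unknown = set(regulator_map) - set(by_id)
    if unknown:
        raise ValueError(f"regulator_map keys not among curves: {sorted(unknown)}")
    r = basis_order
    out = {}
    for focal_id, reg_ids in regulator_map.items():
        focal = by_id[focal_id]
        regs = [by_id[rid] for rid in reg_ids]
        problem = _RK4Problem(focal, regs, r, n_sub=n_sub)

        def unpack(x):
            phi_self = x[: r + 1]
            phi_dep = {rid: x[r + 1 + i * r: r + 1 + (i + 1) * r]
                       for i, rid in enumerate(reg_ids)}
            return phi_self, phi_dep

        def residuals(x):
            phi_self, phi_dep = unpack(x)
            g = problem.dep_drive(phi_dep)
            traj, blew_up = problem.integrate(phi_self, g)
            res = traj[problem.obs_at] - problem.y_obs
            if blew_up:
                res = res + np.sign(res) * 10.0 * (1.0 + np.abs(res))
            return res

        if np.allclose(problem.y_obs, 0.0) and all(
                np.allclose(c.values, 0.0) for c in regs):
            x_fit, obj, ok = np.zeros(r + 1 + r * len(reg_ids)), 0.0, True
        else:
            # two seeded starts: free gradient match, and gradient match
            # with the initial rate pinned (robust against onset-shift
            # local minima); keep the better trajectory optimum
            x_fit, obj, ok = None, math.inf, False
            for pin in (True, False):
                phi_self0, phi_dep0 = _gradient_match_init(problem, regs, r,
                                                           smooth, pin_initial_rate=pin)
                x0 = np.concatenate([phi_self0] + [phi_dep0[rid] for rid in reg_ids])
                sol = least_squares(residuals, x0, method="trf", max_nfev=max_nfev)
                if 2 * sol.cost < obj:
                    x_fit, obj, ok = sol.x, float(2 * sol.cost), bool(sol.status > 0)
        phi_self, phi_dep = unpack(x_fit)
        out[focal_id] = ODEComponentParams(
            qtl_id=focal_id, basis_order=r,
            phi_self=np.asarray(phi_self, float),
            phi_dep={k: np.asarray(v, float) for k, v in phi_dep.items()},
            self_range=problem.self_range, dep_ranges=dict(problem.dep_ranges),
            converged=ok, objective=obj,
        )
    return out


def decompose_effects(params: ODEComponentParams, curves: Sequence[EffectCurve],
                      n_sub: int = 4):
    """Split the fitted trajectory into cumulative component curves.

    Returns ``(independent, dependent, total)`` on the focal's grid:
    ``independent[t] = int_t1^t U_k(P_k)``, ``dependent[rid][t] =
    int_t1^t U_kk'(P_k')`` and ``total`` the fitted trajectory.  The
    identity ``total = P(t1) + independent + sum dependent`` holds to
    machine precision because all parts come from the same RK4 stages.
    """
    by_id = {c.qtl_id: c for c in curves}
    focal = by_id[params.qtl_id]
    regs = [by_id[rid] for rid in params.phi_dep]
    problem = _RK4Problem(focal, regs, params.basis_order, n_sub=n_sub)
    problem.dep_ranges = dict(params.dep_ranges)  # reuse fitted scaling
    g_parts = {rid: problem.reg_basis[rid] @ phi for rid, phi in params.phi_dep.items()}
    g = np.zeros((problem.n_steps, 3))
    for part in g_parts.values():
        g += part
    traj, self_inc, _ = problem.integrate(params.phi_self, g, component_tracking=True)
    independent = np.concatenate([[0.0], np.cumsum(self_inc)])
    dependent = {}
    for rid, part in g_parts.items():
        # same RK4 quadrature weights (1,2,2,1)/6 with stages (t, mid, mid, t+h)
        inc = problem.h / 6.0 * (part[:, 0] + 4.0 * part[:, 1] + part[:, 2])
        dependent[rid] = np.concatenate([[0.0], np.cumsum(inc)])[problem.obs_at]
    return (independent[problem.obs_at], dependent, traj[problem.obs_at])


# ---------------------------------------------------------------------------
# network assembly


@dataclass
class NetworkNode:
    id: str
    qtl_class: str = "piQTL"
    hub: bool = False


@dataclass
class NetworkEdge:
    src: str
    dst: str
    sign: int            # +1 or -1
    weight: float
    curve: np.ndarray | None = None  # dependent-effect curve on the focal grid


@dataclass
class QTLNetwork:
    nodes: list[NetworkNode]
    edges: list[NetworkEdge]
    pair_types: dict[frozenset, str] = field(default_factory=dict)

    def __post_init__(self):
        for e in self.edges:
            if e.src == e.dst:
                raise ValueError("self-edges are not allowed")
            if e.weight <= 0:
                raise ValueError("an edge with zero weight must be absent")

    def edge(self, src: str, dst: str) -> NetworkEdge | None:
        for e in self.edges:
            if e.src == src and e.dst == dst:
                return e
        return None


def _edge_sign(dep_curve: np.ndarray) -> int:
    avg = float(np.mean(dep_curve))
    if avg != 0.0:
        return 1 if avg > 0 else -1
    pos = float(np.sum(dep_curve[dep_curve > 0]))
    neg = float(-np.sum(dep_curve[dep_curve < 0]))
    return 1 if pos >= neg else -1


def infer_network(curves: Sequence[EffectCurve],
                  basis_order: int = 2,
                  lam: float | None = None,
                  n_lambda: int = 20,
                  smooth: bool = True,
                  fit: bool = True,
                  n_sub: int = 4,
                  method: str = "forward") -> QTLNetwork:
    """Full reconstruction: regulator selection, ODE fit, signed weighted edges."""
    ids = [c.qtl_id for c in curves]
    regulator_map = {}
    for c in curves:
        cands = [o for o in curves if o.qtl_id != c.qtl_id]
        regulator_map[c.qtl_id] = select_regulators(
            c, cands, lam=lam, r=basis_order, n_lambda=n_lambda, smooth=smooth,
            method=method)
    nodes = [NetworkNode(id=c.qtl_id, qtl_class=c.qtl_class) for c in curves]
    edges = []
    if fit:
        fits = fit_qdode(curves, regulator_map, basis_order=basis_order,
                         n_sub=n_sub, smooth=smooth)
        for focal_id, p in fits.items():
            if not p.phi_dep:
                continue
            _, dep, _ = decompose_effects(p, curves, n_sub=n_sub)
            problem = _RK4Problem(
                next(c for c in curves if c.qtl_id == focal_id),
                [c for c in curves if c.qtl_id in p.phi_dep], p.basis_order, n_sub)
            for rid, curve in dep.items():
                drive = problem.reg_basis[rid] @ p.phi_dep[rid]
                weight = float(np.mean(np.abs(drive)))
                if weight <= 0:
                    continue
                edges.append(NetworkEdge(src=rid, dst=focal_id,
                                         sign=_edge_sign(curve), weight=weight,
                                         curve=curve))
    else:
        for focal_id, regs in regulator_map.items():
            for rid in regs:
                edges.append(NetworkEdge(src=rid, dst=focal_id, sign=1, weight=1.0))
    net = QTLNetwork(nodes=nodes, edges=edges)
    classify_interactions(net)
    detect_hubs(net)
    return net


def classify_interactions(network: QTLNetwork) -> dict[frozenset, str]:
    """Label every unordered node pair with one of the six interaction types."""
    sign = {(e.src, e.dst): e.sign for e in network.edges}
    labels = {}
    ids = [n.id for n in network.nodes]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            s_ab = sign.get((a, b), 0)
            s_ba = sign.get((b, a), 0)
            labels[frozenset((a, b))] = INTERACTION_LABELS[(s_ab, s_ba)]
    network.pair_types = labels
    return labels


def detect_hubs(network: QTLNetwork) -> list[str]:
    """Nodes whose total degree exceeds the network's mean total degree."""
    if not network.nodes:
        return []
    deg = {n.id: 0 for n in network.nodes}
    for e in network.edges:
        deg[e.src] += 1
        deg[e.dst] += 1
    mean_deg = sum(deg.values()) / len(deg)
    hubs = []
    for n in network.nodes:
        n.hub = bool(network.edges) and deg[n.id] > mean_deg
        if n.hub:
            hubs.append(n.id)
    return hubs


# ---------------------------------------------------------------------------
# serialisation


def export_network(network: QTLNetwork, path, fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV, GraphML or DOT file."""
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("from\tto\tsign\tweight\tpair_type\n")
            for e in network.edges:
                label = network.pair_types.get(frozenset((e.src, e.dst)), "")
                sgn = "+" if e.sign > 0 else "-"
                fh.write(f"{e.src}\t{e.dst}\t{sgn}\t{e.weight!r}\t{label}\n")
        return
    G = nx.DiGraph()
    for n in network.nodes:
        G.add_node(n.id, qtl_class=n.qtl_class, hub=n.hub)
    for e in network.edges:
        G.add_edge(e.src, e.dst, sign=e.sign, weight=e.weight)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph qtl_network {\n")
            for n in network.nodes:
                shape = "doublecircle" if n.hub else "circle"
                fh.write(f'  "{n.id}" [shape={shape}];\n')
            for e in network.edges:
                color = "red" if e.sign > 0 else "blue"
                fh.write(f'  "{e.src}" -> "{e.dst}" [color={color}, penwidth={max(0.5, 4 * e.weight):.3g}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: tsv, graphml, dot")


def read_network(path, nodes: Iterable[str] | None = None) -> QTLNetwork:
    """Read an edge-list TSV written by :func:`export_network`."""
    edges = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["from", "to", "sign", "weight"]:
            raise ValueError("not an allonet edge-list file")
        for line in fh:
            src, dst, sgn, weight, *_rest = line.rstrip("\n").split("\t")
            edges.append(NetworkEdge(src=src, dst=dst,
                                     sign=1 if sgn == "+" else -1,
                                     weight=float(weight)))
            seen.update((src, dst))
    node_ids = list(nodes) if nodes is not None else sorted(seen)
    net = QTLNetwork(nodes=[NetworkNode(id=i) for i in node_ids], edges=edges)
    classify_interactions(net)
    detect_hubs(net)
    return net
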