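"""Validation study: recover a known 14-QTL control network from noisy effect curves.

A designated true network of 14 QTLs (hub Q2 with in-degree zero) is
simulated as a coupled ODE system: each node has a logistic independent
term and each directed edge a linear dependent term,

    dQ_k/dt = alpha_k Q_k (1 - Q_k / K_k) + sum_{k' -> k} beta_{kk'} Q_k'(t).

The study design fixes the topology (18 directed edges out of
14*13 = 182 ordered pairs); the numeric ODE parameters are drawn once
from seeded ranges producing effect-curve magnitudes of order 1-5 trait
units, with logistic onsets staggered evenly across the season (see
:func:`build_true_network`).

Four scenarios cross the number of occasions T in {10, 30} with the
AR(1) residual variance nu2 in {0.05, 0.5}.  Per replicate the
reconstruction pipeline (group-forward regulator selection) is run and
directed-edge recovery is scored: TP, FP, TPR = TP / 18, FPR = FP / 164,
and ROC-AUC from sweeping a threshold over the forward-path gain scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import rankdata

from .covariance import AR1Params, ar1_matrix
from .funmap import EffectCurve
from .netode import QTLNetwork, forward_select

logger = logging.getLogger(__name__)

__all__ = [
    "TrueNetworkSpec",
    "SimScenario",
    "EvalMetrics",
    "build_true_network",
    "solve_true_system",
    "true_components",
    "simulate_network_data",
    "detect_and_score",
    "evaluate_network",
    "run_scenarios",
    "DEFAULT_SCENARIOS",
]

HUB_NODE = "Q2"
# minimal reading of the designated topology: elided regulator lists are
# taken at their printed endpoints
TRUE_EDGES: tuple[tuple[str, str], ...] = tuple(
    (f"Q{src}", f"Q{dst}")
    for src, targets in ((2, (1, 3, 4, 5, 6, 7, 11, 12, 13)),
                         (10, (3, 4, 9, 11)),
                         (13, (8, 9, 10, 12, 14)))
    for dst in targets
)
N_NODES = 14


@dataclass
class TrueNetworkSpec:
    """Ground-truth 14-node system with per-node logistic and per-edge linear terms."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    alpha: dict[str, float]
    capacity: dict[str, float]
    beta: dict[tuple[str, str], float]
    q0: dict[str, float]
    t_span: tuple[float, float] = (0.0, 10.0)
    hub: str = HUB_NODE

    def in_edges(self, node: str) -> list[tuple[str, str]]:
        return [e for e in self.edges if e[1] == node]


@dataclass
class SimScenario:
    T: int
    nu2: float
    rho: float = 0.5
    replicates: int = 100
    seed: int = 0


@dataclass
class EvalMetrics:
    TP: float
    FP: float
    TPR: float
    FPR: float
    AUC: float

    def __post_init__(self):
        for name in ("TPR", "FPR", "AUC"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"{name} = {v} outside [0, 1]")


def build_true_network(
    seed: int = 7,
    alpha_range: tuple[float, float] = (1.5, 2.5),
    capacity_range: tuple[float, float] = (2.0, 4.0),
    beta_magnitude_range: tuple[float, float] = (0.15, 0.35),
    onset_range: tuple[float, float] = (0.5, 9.5),
    t_span: tuple[float, float] = (0.0, 10.0),
    edges: list[tuple[str, str]] | None = None,
    max_redraws: int = 500,
) -> TrueNetworkSpec:
    """Draw a ground-truth parameterisation of the designated 14-QTL topology.

    Each node's independent term is logistic with rate ``alpha`` and
    carrying capacity drawn from the given ranges; the initial value is
    set so the logistic midpoint (the effect's "onset") falls at a
    per-node time.  Onsets are spaced evenly over ``onset_range`` and
    assigned to nodes in seeded random order: staggering the onsets
    across the season makes the fourteen effect trajectories mutually
    distinguishable, the regime in which directed-edge recovery is
    informative (clumped onsets make co-regulated curves collinear and
    the reconstruction problem degenerate).  Dependent terms are linear
    with signed magnitudes from ``beta_magnitude_range``, giving effect
    curves of magnitude roughly 2-5 trait units.

    The hub has in-degree zero by design; a custom edge list that points
    into the hub is rejected.  Parameter draws under which the coupled
    system blows up (|Q| > 20) or stays degenerate (max |Q| < 1.5) are
    redrawn with a logged count, up to ``max_redraws`` times.
    """
    nodes = [f"Q{i}" for i in range(1, N_NODES + 1)]
    edge_list = list(TRUE_EDGES) if edges is None else list(edges)
    for src, dst in edge_list:
        if src == dst:
            raise ValueError("self-edges are not allowed in the true network")
        if dst == HUB_NODE:
            raise ValueError(f"the hub {HUB_NODE} must have in-degree zero")
    rng = np.random.default_rng(seed)
    for attempt in range(max_redraws + 1):
        onsets = np.linspace(*onset_range, len(nodes))
        rng.shuffle(onsets)
        alpha = {n: rng.uniform(*alpha_range) for n in nodes}
        capacity = {n: rng.uniform(*capacity_range) for n in nodes}
        q0 = {n: capacity[n] / (1.0 + math.exp(alpha[n] * onsets[i]))
              for i, n in enumerate(nodes)}
        beta = {}
        for e in edge_list:
            mag = rng.uniform(*beta_magnitude_range)
            beta[e] = mag * (1 if rng.random() < 0.5 else -1)
        spec = TrueNetworkSpec(nodes=nodes, edges=edge_list, alpha=alpha,
                               capacity=capacity, beta=beta, q0=q0, t_span=t_span)
        try:
            t, Q = solve_true_system(spec, n_points=101)
        except RuntimeError:
            continue
        if np.all(np.isfinite(Q)) and 1.5 <= np.max(np.abs(Q)) <= 20.0:
            if attempt:
                logger.info("true-parameter draw accepted after %d redraws", attempt)
            return spec
    raise RuntimeError("could not draw a stable true parameterisation")


def _rhs(spec: TrueNetworkSpec):
    idx = {n: i for i, n in enumerate(spec.nodes)}
    alpha = np.array([spec.alpha[n] for n in spec.nodes])
    cap = np.array([spec.capacity[n] for n in spec.nodes])
    B = np.zeros((N_NODES, N_NODES))
    for (src, dst), b in spec.beta.items():
        B[idx[dst], idx[src]] = b

    def f(t, q):
        return alpha * q * (1.0 - q / cap) + B @ q

    return f


def solve_true_system(spec: TrueNetworkSpec, T: int | None = None,
                      n_points: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free solution of the coupled system at T (or n_points) occasions.

    Returns ``(t, Q)`` with Q of shape (n_nodes, len(t)).
    """
    n_eval = T if T is not None else (n_points or 101)
    t = np.linspace(*spec.t_span, n_eval)
    q0 = np.array([spec.q0[n] for n in spec.nodes])
    sol = solve_ivp(_rhs(spec), spec.t_span, q0, t_eval=t, rtol=1e-9, atol=1e-11)
    if not sol.success or sol.y.shape[1] != n_eval:
        raise RuntimeError("true system blew up before the end of the time span")
    return t, sol.y


def true_components(spec: TrueNetworkSpec, T: int, n_dense: int = 601):
    """True cumulative independent/dependent component curves on the T-grid.

    Computed by trapezoid quadrature of the true rate terms along a dense
    solution, then sampled at the T occasions.  Returns
    ``(independent, dependent)`` where ``independent[node]`` is a length-T
    array and ``dependent[(src, dst)]`` likewise.
    """
    t_dense, Q = solve_true_system(spec, n_points=n_dense)
    t_obs = np.linspace(*spec.t_span, T)
    idx = {n: i for i, n in enumerate(spec.nodes)}

    def cumint(rate):
        out = np.concatenate([[0.0], np.cumsum(np.diff(t_dense) * (rate[:-1] + rate[1:]) / 2.0)])
        return np.interp(t_obs, t_dense, out)

    # dependent components are anchored at the regulator's initial level
    # (U_kk' = 0 where Q' = Q'(t1)), matching the estimator's convention;
    # the constant b * Q'(t1) stays with the focal's independent part
    independent = {}
    for n in spec.nodes:
        q = Q[idx[n]]
        base = sum(b * Q[idx[src]][0] for (src, dst), b in spec.beta.items() if dst == n)
        independent[n] = cumint(spec.alpha[n] * q * (1.0 - q / spec.capacity[n]) + base)
    dependent = {}
    for (src, dst), b in spec.beta.items():
        dependent[(src, dst)] = cumint(b * (Q[idx[src]] - Q[idx[src]][0]))
    return independent, dependent


def simulate_network_data(spec: TrueNetworkSpec, scen: SimScenario,
                          rng: np.random.Generator | None = None):
    """One replicate: noise-free truth plus AR(1) Gaussian residuals per curve.

    Returns ``(curves, truth)`` as lists of :class:`EffectCurve` on the
    scenario's T-occasion grid.
    """
    if rng is None:
        rng = np.random.default_rng(scen.seed)
    t, Q = solve_true_system(spec, T=scen.T)
    truth = [EffectCurve(qtl_id=n, qtl_class="piQTL", grid=t,
                         predictor_mean=t, values=Q[i])
             for i, n in enumerate(spec.nodes)]
    if scen.nu2 == 0:
        noisy = Q.copy()
    else:
        cov = ar1_matrix(AR1Params(rho=scen.rho, sigma2=scen.nu2), scen.T)
        chol = np.linalg.cholesky(cov)
        noisy = Q + rng.standard_normal((N_NODES, scen.T)) @ chol.T
    curves = [EffectCurve(qtl_id=n, qtl_class="piQTL", grid=t,
                          predictor_mean=t, values=noisy[i])
              for i, n in enumerate(spec.nodes)]
    return curves, truth


def detect_and_score(curves: list[EffectCurve], basis_order: int = 2,
                     smooth: bool = True, max_regulators: int = 3,
                     ebic_gamma: float = 1.0):
    """Edge detection plus continuous per-edge evidence, one selection per focal.

    Runs greedy group-forward selection with the EBIC stop for every
    focal QTL.  Returns ``(detected, scores)``: the selected directed
    edge set and a score for every ordered pair (src, dst) — the log
    rss gain of src on dst's forward path.
    """
    detected = set()
    scores: dict[tuple[str, str], float] = {}
    for focal in curves:
        cands = [c for c in curves if c.qtl_id != focal.qtl_id]
        selected, sc = forward_select(focal, cands, r=basis_order, smooth=smooth,
                                      max_regulators=max_regulators,
                                      ebic_gamma=ebic_gamma)
        for cid, val in sc.items():
            scores[(cid, focal.qtl_id)] = val
        for cid in selected:
            detected.add((cid, focal.qtl_id))
    return detected, scores


def _roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with mid-rank tie handling."""
    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_network(inferred, truth: TrueNetworkSpec,
                     score_curve: dict[tuple[str, str], float] | None = None) -> EvalMetrics:
    """Score directed-edge recovery of one inferred network against truth.

    ``inferred`` is either a :class:`QTLNetwork` or a set of (src, dst)
    pairs.  TPR uses the number of true edges as denominator and FPR the
    number of true non-edges (ordered pairs, no self-pairs).  AUC needs
    ``score_curve`` (per ordered pair); NaN when absent.
    """
    if isinstance(inferred, QTLNetwork):
        node_ids = {n.id for n in inferred.nodes}
        if node_ids != set(truth.nodes):
            raise ValueError("inferred and true node sets differ")
        detected = {(e.src, e.dst) for e in inferred.edges}
    else:
        detected = set(inferred)
        for src, dst in detected:
            if src not in truth.nodes or dst not in truth.nodes:
                raise ValueError(f"edge ({src}, {dst}) outside the true node set")
    true_set = set(truth.edges)
    all_pairs = [(a, b) for a in truth.nodes for b in truth.nodes if a != b]
    n_true = len(true_set)
    n_null = len(all_pairs) - n_true
    tp = len(detected & true_set)
    fp = len(detected - true_set)
    if score_curve is not None:
        labels = np.array([p in true_set for p in all_pairs])
        scores = np.array([score_curve.get(p, 0.0) for p in all_pairs])
        auc = _roc_auc(labels, scores)
    else:
        auc = math.nan
    return EvalMetrics(TP=tp, FP=fp, TPR=tp / n_true, FPR=fp / n_null, AUC=auc)


DEFAULT_SCENARIOS = (
    SimScenario(T=10, nu2=0.05),
    SimScenario(T=10, nu2=0.5),
    SimScenario(T=30, nu2=0.05),
    SimScenario(T=30, nu2=0.5),
)


def run_scenarios(spec: TrueNetworkSpec | None = None,
                  scenarios=DEFAULT_SCENARIOS,
                  replicates: int = 100,
                  seed: int = 0,
                  rho: float = 0.5,
                  basis_order: int = 2,
                  return_replicates: bool = False):
    """Run the full scenario grid and aggregate recovery metrics.

    Returns a table with one row per scenario: mean (sd) of TP, FP, TPR,
    FPR and AUC over replicates; with ``return_replicates`` a second
    per-replicate table is returned as well.  Fully seeded; identical
    seeds give bit-identical tables.  Replicate failures are recorded and
    skipped; a scenario with > 20% failures is flagged invalid.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if spec is None:
        spec = build_true_network()
    rows = []
    rep_rows = []
    for scen_idx, scen in enumerate(scenarios):
        scen = SimScenario(T=scen.T, nu2=scen.nu2, rho=rho,
                           replicates=replicates, seed=seed)
        rep_seeds = np.random.SeedSequence([seed, scen_idx]).spawn(replicates)
        metrics, failures = [], 0
        for rep in range(replicates):
            try:
                rng = np.random.default_rng(rep_seeds[rep])
                curves, _ = simulate_network_data(spec, scen, rng=rng)
                detected, scores = detect_and_score(curves, basis_order=basis_order)
                m = evaluate_network(detected, spec, score_curve=scores)
                metrics.append(m)
                rep_rows.append({"nu2": scen.nu2, "T": scen.T, "replicate": rep,
                                 "TP": m.TP, "FP": m.FP, "TPR": m.TPR,
                                 "FPR": m.FPR, "AUC": m.AUC})
            except Exception as exc:  # pragma: no cover - defensive
                failures += 1
                logger.warning("replicate %d of scenario (nu2=%s, T=%s) failed: %s",
                               rep, scen.nu2, scen.T, exc)
        valid = failures <= 0.2 * replicates and metrics
        row = {"nu2": scen.nu2, "T": scen.T, "replicates": len(metrics),
               "failures": failures, "valid": bool(valid)}
        for name in ("TP", "FP", "TPR", "FPR", "AUC"):
            vals = np.array([getattr(m, name) for m in metrics], dtype=float)
            row[name] = float(np.mean(vals)) if metrics else math.nan
            row[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if return_replicates:
        return table, pd.DataFrame(rep_rows)
    return table


def format_report(table: pd.DataFrame) -> str:
    """Pretty mean (sd) rendering of a :func:`run_scenarios` table."""
    lines = ["# TPR = TP / |true edges|; FPR = FP / |true non-edges|",
             "nu2\tT\tTP\tFP\tTPR\tFPR\tAUC"]
    for _, r in table.iterrows():
        cells = [f"{r['nu2']:g}", f"{int(r['T'])}"]
        for name in ("TP", "FP", "TPR", "FPR", "AUC"):
            cells.append(f"{r[name]:.2f} ({r[f'{name}_sd']:.2f})")
        lines.append("\t".join(cells))
    return "\n".join(lines)
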