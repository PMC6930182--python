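"""Functional mapping of height-diameter allometry QTLs in a full-sib family.

Each SNP splits the progeny into genotype classes (two for a testcross
marker, three for an intercross marker).  Under the alternative every
class gets its own allometry coefficient triple (a, b, d); under the null
all progeny share one triple.  The genotypic mean of individual *i* at
occasion *t* is the allometry equation evaluated at that individual's
*observed* co-trait value at *t*, and residual vectors are scored with a
shared stationary AR(1) Gaussian likelihood.  Twice the log-likelihood
ratio is referred to a chi-square distribution with 3(J - 1) degrees of
freedom.

Two scan directions are supported:

* ``PI`` — response height, predictor diameter; significant markers are
  "pioneering" QTLs (piQTLs) that modulate how height growth scales with
  diameter growth.
* ``MI`` — response diameter, predictor height; significant markers are
  "maintaining" QTLs (miQTLs) controlling the reverse scaling.

The per-individual baseline ``h0`` is that individual's first height
observation.  Because the height at the baseline occasion carries no
information about the scaling (the response equals the baseline in the PI
direction, and the predictor equals it in the MI direction, putting it on
the boundary of the log domain), the first occasion is dropped from the
likelihood in both directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .allometry import AllometryParams, Direction, _initial_guess, eval_mean
from .covariance import AR1Params

logger = logging.getLogger(__name__)

__all__ = [
    "CrossType",
    "ScanDirection",
    "MarkerRecord",
    "MappingPopulation",
    "MarkerSkipped",
    "EffectCurve",
    "ScanResult",
    "FunmapFit",
    "genotype_groups",
    "fit_funmap",
    "lr_scan",
    "bonferroni_thresholds",
    "effect_curves",
]

_PENALTY = 1e12
MISSING_CODES = {"", "na", "NA", "--", "-", None}
TESTCROSS_CODES = ("nn", "np")
INTERCROSS_CODES = ("aa", "ab", "bb")


class CrossType(str, Enum):
    TESTCROSS = "testcross"  # one parent heterozygous: 2 offspring classes, 1:1
    INTERCROSS = "intercross"  # both parents heterozygous: 3 classes, 1:2:1


class ScanDirection(str, Enum):
    PI = "PI"  # height response, diameter predictor  -> piQTLs
    MI = "MI"  # diameter response, height predictor  -> miQTLs

    @property
    def allometry_direction(self) -> Direction:
        return Direction.H_FROM_D if self is ScanDirection.PI else Direction.D_FROM_H

    @property
    def qtl_class(self) -> str:
        return "piQTL" if self is ScanDirection.PI else "miQTL"


class MarkerSkipped(ValueError):
    """Marker cannot be tested (monomorphic or under-replicated class)."""


@dataclass
class MarkerRecord:
    id: str
    chrom: str
    pos: int
    cross_type: CrossType
    codes: Sequence[str]

    def observed_codes(self) -> list[str]:
        return [c for c in self.codes if c not in MISSING_CODES]


@dataclass
class MappingPopulation:
    """Longitudinal height/diameter matrices plus marker genotypes for a full-sib family."""

    heights: np.ndarray  # (n, T) in cm, NaN = missing
    diameters: np.ndarray  # (n, T) in mm, NaN = missing
    markers: list[MarkerRecord] = field(default_factory=list)
    family_id: str = "synthetic"
    ids: list[str] | None = None

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.heights.shape != self.diameters.shape:
            raise ValueError("height and diameter matrices must share shape (n, T)")
        if self.ids is None:
            self.ids = [f"ind{i + 1}" for i in range(self.n)]
        obs = np.isfinite(self.heights) & np.isfinite(self.diameters)
        if np.any(obs.sum(axis=1) < 2):
            raise ValueError("every individual needs >= 2 complete occasions")
        with np.errstate(invalid="ignore"):
            if np.any(self.heights[np.isfinite(self.heights)] <= 0):
                raise ValueError("heights must be strictly positive")

    @property
    def n(self) -> int:
        return self.heights.shape[0]

    @property
    def T(self) -> int:
        return self.heights.shape[1]

    @property
    def h0(self) -> np.ndarray:
        """Per-individual baseline: the first height observation."""
        first = np.argmax(np.isfinite(self.heights), axis=1)
        return self.heights[np.arange(self.n), first]


def genotype_groups(marker: MarkerRecord, min_count: int = 10) -> list[np.ndarray]:
    """Partition individual indices by genotype code, dropping missing codes.

    Groups are returned in canonical code order (nn, np / aa, ab, bb).
    Raises :class:`MarkerSkipped` for monomorphic markers or any observed
    class below ``min_count``.
    """
    order = TESTCROSS_CODES if marker.cross_type == CrossType.TESTCROSS else INTERCROSS_CODES
    codes = [str(c).strip().lower() if c is not None else "" for c in marker.codes]
    unknown = sorted({c for c in codes if c and c not in MISSING_CODES and c not in order})
    if unknown:
        raise ValueError(
            f"marker {marker.id}: unknown genotype code(s) {unknown} for {marker.cross_type.value}"
        )
    groups = []
    for code in order:
        idx = np.array([i for i, c in enumerate(codes) if c == code], dtype=int)
        if idx.size:
            groups.append((code, idx))
    if len(groups) < 2:
        raise MarkerSkipped(f"marker {marker.id}: monomorphic ({len(groups)} class)")
    small = [code for code, idx in groups if idx.size < min_count]
    if small:
        raise MarkerSkipped(
            f"marker {marker.id}: class(es) {small} below minimum count {min_count}"
        )
    return [idx for _, idx in groups]


# ---------------------------------------------------------------------------
# likelihood machinery


class _LikelihoodData:
    """Pre-extracted response/predictor blocks for one set of genotype groups.

    The baseline occasion is dropped; within the remaining block, occasions
    where the predictor leaves the equation's domain (possible in the MI
    direction when noise pushes a height below the baseline) are masked out
    and scored with the AR(1) sub-vector likelihood.
    """

    def __init__(self, pop: MappingPopulation, groups: list[np.ndarray], direction: ScanDirection):
        self.direction = direction
        h0 = pop.h0
        if direction == ScanDirection.PI:
            resp, pred = pop.heights, pop.diameters
        else:
            resp, pred = pop.diameters, pop.heights
        self.blocks = []
        for idx in groups:
            y = resp[idx, 1:]
            x = pred[idx, 1:]
            b = h0[idx][:, None]
            valid = np.isfinite(y) & np.isfinite(x)
            if direction == ScanDirection.MI:
                valid &= x > b + 1e-9
            # fill masked predictor cells with an in-domain placeholder so a
            # parameter proposal is only penalised for *observed* cells
            if direction == ScanDirection.PI:
                fill = float(np.mean(x[valid])) if valid.any() else 1.0
                x_filled = np.where(valid, x, fill)
            else:
                excess = float(np.mean((x - b)[valid])) if valid.any() else 1.0
                x_filled = np.where(valid, x, b + max(excess, 1e-3))
            complete = valid.all(axis=1)
            self.blocks.append((y, x_filled, b, valid, complete, bool(complete.all())))
        self.n_obs = int(sum(v.sum() for _, _, _, v, _, _ in self.blocks))

    def residuals(self, thetas: list[np.ndarray]):
        """Masked residual matrices per group, or None if out of domain."""
        out = []
        for theta, (y, x_filled, b, valid, _c, _ac) in zip(thetas, self.blocks):
            mu = eval_mean(theta, b, x_filled, self.direction.allometry_direction)
            if mu is None:
                return None
            r = np.where(valid, y - mu, np.nan)
            out.append(r)
        return out


def _ar1_gapped_terms(r_row: np.ndarray, rho: float):
    """(quadform, logdet1) of one possibly gapped residual row under AR(1).

    Uses the innovation form: observed occasions s_1 < ... < s_m have
    correlations rho^(s_{k+1}-s_k}); the process stays Markov on the
    observed subsequence.
    """
    obs = np.flatnonzero(np.isfinite(r_row))
    r = r_row[obs]
    if r.size == 0:
        return 0.0, 0.0
    gaps = np.diff(obs)
    rg = rho ** gaps
    one_m = 1.0 - rg * rg
    innov = r[1:] - rg * r[:-1]
    q = r[0] ** 2 + float(np.sum(innov * innov / one_m))
    logdet1 = float(np.sum(np.log(one_m)))
    return q, logdet1


def _profiled_loglik(res_blocks: list[np.ndarray], rho: float, n_obs: int):
    """Max over sigma2 of the AR(1) log-likelihood of the residual blocks."""
    q_tot = 0.0
    logdet1 = 0.0
    for r in res_blocks:
        complete = np.all(np.isfinite(r), axis=1)
        rc = r[complete]
        if rc.size:
            T = rc.shape[1]
            if T == 1:
                q_tot += float(np.sum(rc * rc))
            else:
                innov = rc[:, 1:] - rho * rc[:, :-1]
                q_tot += float(np.sum(rc[:, 0] ** 2)) + float(np.sum(innov * innov)) / (1 - rho * rho)
                logdet1 += rc.shape[0] * (T - 1) * math.log1p(-rho * rho)
        for row in r[~complete]:
            q, ld = _ar1_gapped_terms(row, rho)
            q_tot += q
            logdet1 += ld
    if q_tot <= 0 or not math.isfinite(q_tot):
        return None
    sigma2 = max(q_tot / n_obs, 1e-12)
    ll = -0.5 * (
        n_obs * math.log(2 * math.pi)
        + n_obs * math.log(sigma2)
        + logdet1
        + q_tot / sigma2
    )
    return ll, sigma2


@dataclass
class FunmapFit:
    params_by_group: list[AllometryParams]
    ar1: AR1Params
    loglik: float
    converged: bool


def _block_quadform(theta: np.ndarray, block, rho: float, direction: ScanDirection):
    """AR(1) quadratic form (sigma2 = 1) of one group's residuals, or None."""
    y, x_filled, b, valid, complete, all_complete = block
    mu = eval_mean(theta, b, x_filled, direction.allometry_direction)
    if mu is None:
        return None
    r = y - mu
    q = 0.0
    logdet1 = 0.0
    rc = r if all_complete else r[complete]
    if rc.size:
        T = rc.shape[1]
        if T == 1:
            q += float(np.sum(rc * rc))
        else:
            innov = rc[:, 1:] - rho * rc[:, :-1]
            q += float(rc[:, 0] @ rc[:, 0]) + float(np.sum(innov * innov)) / (1 - rho * rho)
            logdet1 += rc.shape[0] * (T - 1) * math.log1p(-rho * rho)
    if not all_complete:
        rm = np.where(valid, r, np.nan)
        for row in rm[~complete]:
            qi, ld = _ar1_gapped_terms(row, rho)
            q += qi
            logdet1 += ld
    if not math.isfinite(q):
        return None
    return q, logdet1


def fit_funmap(
    pop: MappingPopulation,
    groups: list[np.ndarray],
    direction: ScanDirection,
    init: list[AllometryParams] | None = None,
    init_rho: float = 0.3,
    seed: int = 0,
    max_retries: int = 5,
    max_cycles: int = 8,
    tol: float = 1e-7,
) -> FunmapFit:
    """Maximise the AR(1) functional-mapping likelihood over per-group (a, b, d).

    The AR(1) variance is profiled out analytically, and the remaining
    parameters are maximised by blockwise coordinate ascent: with rho held
    fixed, genotype groups decouple and each (a, b, d) triple is updated
    by a 3-parameter simplex; rho is then re-profiled by a bounded scalar
    search.  Every step is monotone in the profiled likelihood, so a fit
    warm-started at the null solution can never fall below it.  With
    ``groups=[all]`` this is the null fit; with J genotype groups the
    alternative (nested by construction).  On failure to reach the
    equation's domain the cycle restarts from up to ``max_retries``
    jittered starts (seeded).
    """
    from scipy.optimize import minimize_scalar

    dirn = direction.allometry_direction
    J = len(groups)
    data = _LikelihoodData(pop, groups, direction)
    if data.n_obs < 3 * J + 2:
        raise ValueError("not enough observations to fit the model")
    N = data.n_obs

    def total_loglik(thetas, rho):
        q_tot, logdet1 = 0.0, 0.0
        for theta, block in zip(thetas, data.blocks):
            out = _block_quadform(theta, block, rho, direction)
            if out is None:
                return None
            q_tot += out[0]
            logdet1 += out[1]
        if q_tot <= 0:
            return None
        sigma2 = max(q_tot / N, 1e-12)
        ll = -0.5 * (N * math.log(2 * math.pi) + N * math.log(sigma2) + logdet1 + q_tot / sigma2)
        return ll, sigma2

    if init is not None:
        thetas0 = [p.as_vector().copy() for p in init]
    else:
        h0 = pop.h0
        thetas0 = []
        for idx, (y, x, b, valid, _c, _ac) in zip(groups, data.blocks):
            m = valid.ravel()
            thetas0.append(
                _initial_guess(x.ravel()[m], y.ravel()[m], float(np.mean(h0[idx])), dirn)
            )

    rng = np.random.default_rng(seed)
    best_state = None  # (ll, thetas, rho, sigma2)
    for attempt in range(max_retries + 1):
        if attempt == 0:
            thetas = [t.copy() for t in thetas0]
        else:
            thetas = [t * (1 + 0.1 * rng.standard_normal(3)) + 0.05 * rng.standard_normal(3)
                      for t in thetas0]
        rho = init_rho
        cur = total_loglik(thetas, rho)
        ll_prev = cur[0] if cur is not None else -math.inf
        ok = True
        for cycle in range(max_cycles):
            for j, block in enumerate(data.blocks):
                def q_obj(theta, _block=block):
                    out = _block_quadform(theta, _block, rho, direction)
                    return out[0] if out is not None else _PENALTY

                res = minimize(q_obj, thetas[j], method="Nelder-Mead",
                               options={"maxiter": 600, "xatol": 1e-7, "fatol": 1e-9})
                if res.fun < q_obj(thetas[j]):
                    thetas[j] = np.asarray(res.x)

            def rho_obj(r):
                out = total_loglik(thetas, r)
                return -out[0] if out is not None else _PENALTY

            sres = minimize_scalar(rho_obj, bounds=(-0.99, 0.99), method="bounded",
                                   options={"xatol": 1e-6})
            if sres.fun < rho_obj(rho):
                rho = float(sres.x)
            cur = total_loglik(thetas, rho)
            if cur is None:
                ok = False
                break
            if cur[0] - ll_prev < tol and cycle > 0:
                ll_prev = cur[0]
                break
            ll_prev = cur[0]
        if ok and cur is not None:
            if best_state is None or cur[0] > best_state[0]:
                best_state = (cur[0], [t.copy() for t in thetas], rho, cur[1])
            break
        if best_state is not None:
            break

    converged = best_state is not None
    if not converged:
        logger.warning("fit_funmap failed to find an in-domain optimum")
        best_state = (-_PENALTY, thetas0, init_rho, 1.0)
    ll, thetas, rho, sigma2 = best_state
    params = [
        AllometryParams(direction=dirn, h0=float(np.mean(pop.h0[idx])),
                        a=float(t[0]), b=float(t[1]), d=float(t[2]))
        for idx, t in zip(groups, thetas)
    ]
    return FunmapFit(params_by_group=params, ar1=AR1Params(rho=rho, sigma2=sigma2),
                     loglik=float(ll), converged=converged)


@dataclass
class ScanResult:
    marker: MarkerRecord
    direction: ScanDirection
    null_fit: FunmapFit
    alt_fit: FunmapFit
    LR: float
    df: int
    p: float
    significant: bool = False
    skipped: bool = False
    skip_reason: str = ""

    @property
    def neglog10p(self) -> float:
        return float(-np.log10(max(self.p, 1e-300)))


def lr_scan(
    pop: MappingPopulation,
    direction: ScanDirection,
    min_count: int = 10,
    seed: int = 0,
    markers: Sequence[MarkerRecord] | None = None,
) -> list[ScanResult]:
    """Likelihood-ratio scan over all markers in one direction.

    The null fit depends only on which individuals carry a genotype call,
    so it is cached per missingness pattern.  Markers that fail the
    genotype-class requirements yield placeholder results flagged
    ``skipped`` (excluded from thresholds).  Raises if every marker is
    skipped.
    """
    markers = list(pop.markers if markers is None else markers)
    null_cache: dict[tuple, FunmapFit] = {}
    results = []
    for marker in markers:
        try:
            groups = genotype_groups(marker, min_count=min_count)
        except MarkerSkipped as exc:
            logger.info("skipping %s: %s", marker.id, exc)
            results.append(
                ScanResult(marker, direction, None, None, math.nan, 0, math.nan,
                           skipped=True, skip_reason=str(exc))
            )
            continue
        tested = np.sort(np.concatenate(groups))
        key = tested.tobytes()
        if key not in null_cache:
            null_cache[key] = fit_funmap(pop, [tested], direction, seed=seed)
        h0_fit = null_cache[key]
        # warm-start each genotype class at the null solution: the
        # alternative then starts exactly at the null likelihood, which
        # guarantees LR >= 0 up to simplex slack
        init = [h0_fit.params_by_group[0]] * len(groups)
        h1_fit = fit_funmap(pop, groups, direction, init=init,
                            init_rho=h0_fit.ar1.rho, seed=seed)
        LR = max(2.0 * (h1_fit.loglik - h0_fit.loglik), 0.0)
        df = 3 * (len(groups) - 1)
        p = float(chi2.sf(LR, df))
        results.append(ScanResult(marker, direction, h0_fit, h1_fit, LR, df, p))
    if all(r.skipped for r in results):
        raise MarkerSkipped("all markers were skipped; nothing to scan")
    return results


def bonferroni_thresholds(
    results: list[ScanResult],
    alpha: float = 0.05,
    per_cross_type: bool = True,
) -> dict[CrossType, float]:
    """Per-test significance levels alpha / (number of markers of each cross type).

    Sets the ``significant`` flag on each (non-skipped) result and returns
    the per-type level; a cross type with zero testable markers maps to
    NaN.  With ``per_cross_type=False`` a single combined Bonferroni level
    is applied to both types.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    tested = [r for r in results if not r.skipped]
    levels: dict[CrossType, float] = {}
    for ct in CrossType:
        n_ct = sum(1 for r in tested if r.marker.cross_type == ct)
        if per_cross_type:
            levels[ct] = alpha / n_ct if n_ct else math.nan
        else:
            levels[ct] = alpha / len(tested) if tested else math.nan
    for r in tested:
        level = levels[r.marker.cross_type]
        r.significant = bool(not math.isnan(level) and r.p < level)
    return levels


@dataclass
class EffectCurve:
    """A QTL's time-indexed genetic-effect trajectory.

    ``grid`` carries the measurement occasions used (1-based, baseline
    occasion excluded) and ``predictor_mean`` the population-mean co-trait
    value at each, so the curve can be plotted against time or against the
    predictor.  For intercross QTLs ``values`` is the additive effect and
    ``components`` holds the additive/dominant sub-curves.
    """

    qtl_id: str
    qtl_class: str
    grid: np.ndarray
    predictor_mean: np.ndarray
    values: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    genotype_means: dict[str, np.ndarray] = field(default_factory=dict)


def effect_curves(
    pop: MappingPopulation,
    marker: MarkerRecord,
    alt_fit: FunmapFit,
    direction: ScanDirection,
    min_count: int = 10,
) -> EffectCurve:
    """Genetic-effect curve of a QTL from its genotype-specific mean curves.

    The genotype mean at occasion t is the fitted allometry equation
    averaged over the individuals of that genotype, each evaluated at its
    own observed predictor value.  Testcross: effect = class1 - class2.
    Intercross: additive = homozygote(aa) - heterozygote, dominant =
    heterozygote - (aa + bb)/2.
    """
    groups = genotype_groups(marker, min_count=min_count)
    if len(groups) != len(alt_fit.params_by_group):
        raise ValueError("alt_fit does not match the marker's genotype classes")
    data = _LikelihoodData(pop, groups, direction)
    h0 = pop.h0
    code_order = TESTCROSS_CODES if marker.cross_type == CrossType.TESTCROSS else INTERCROSS_CODES
    means = {}
    pred_accum = []
    for code, idx, params, (y, x_filled, b, valid, _c, _ac) in zip(code_order, groups, alt_fit.params_by_group, data.blocks):
        xs = np.where(valid, x_filled, np.nan)
        mu = eval_mean(params.as_vector(), h0[idx][:, None], x_filled, direction.allometry_direction)
        if mu is None:
            raise ValueError("fitted parameters out of domain on observed predictors")
        mu = np.where(valid, mu, np.nan)
        means[code] = np.nanmean(mu, axis=0)
        pred_accum.append(xs)
    grid = np.arange(2, pop.T + 1)
    predictor_mean = np.nanmean(np.vstack(pred_accum), axis=0)
    if marker.cross_type == CrossType.TESTCROSS:
        values = means["nn"] - means["np"]
        components = {}
    else:
        add = means["aa"] - means["ab"]
        dom = means["ab"] - 0.5 * (means["aa"] + means["bb"])
        values = add
        components = {"additive": add, "dominant": dom}
    return EffectCurve(
        qtl_id=marker.id,
        qtl_class=direction.qtl_class,
        grid=grid,
        predictor_mean=predictor_mean,
        values=values,
        components=components,
        genotype_means=means,
    )
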