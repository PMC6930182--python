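"""Synthetic full-sib mapping populations with planted allometry QTLs.

Emulates the data layout of a biweekly shoot-growth trial on a full-sib
family: each progeny is measured for shoot height (cm) and basal diameter
(mm) at T common occasions, and genotyped at unlinked SNP markers that
are either testcross (two classes, 1:1) or intercross (three classes,
1:2:1).

Diameter is generated mechanistically as per-individual logistic growth
with jittered rate/asymptote, so the two scan directions are not
trivially symmetric.  Height follows the allometry equation of the
individual's diameter plus a stationary AR(1) Gaussian residual; a
planted piQTL makes the (a, b, d) triple genotype-specific.  A planted
miQTL works symmetrically: the diameter trait is regenerated from the
heights through the genotype-specific reverse equation plus AR(1) noise.

Defaults are sized like a real trial: 180 progeny, 12 biweekly occasions,
and a rate coefficient ``d`` strongly negative so the height curve rises
from near the baseline toward its asymptote over the observed diameter
range (making the first observation an honest baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allometry import AllometryParams, Direction
from .covariance import AR1Params, ar1_matrix
from .funmap import (
    CrossType,
    MappingPopulation,
    MarkerRecord,
    ScanDirection,
)

__all__ = ["CausalQtlSpec", "default_genotype_params", "simulate_population"]

BASELINE_H = AllometryParams(Direction.H_FROM_D, h0=0.0, a=4.0, b=1.0, d=-18.0)
BASELINE_D = AllometryParams(Direction.D_FROM_H, h0=0.0, a=4.0, b=1.0, d=18.0)


@dataclass
class CausalQtlSpec:
    """A marker with genotype-specific allometry parameters.

    ``genotype_params`` maps each genotype code of the cross type to the
    (a, b, d) triple used to generate that class's trait values; a marker
    whose classes share one triple is a planted null.
    """

    marker_index: int
    cross_type: CrossType
    direction: ScanDirection
    genotype_params: dict[str, AllometryParams] = field(default_factory=dict)


def default_genotype_params(direction: ScanDirection = ScanDirection.PI,
                            a_shift: float = 0.3) -> dict[str, AllometryParams]:
    """Testcross genotype parameter pair differing by ``a_shift`` in ``a``.

    Shifting ``a`` moves the late-stage asymptote, the component of the
    scaling curve a QTL most plausibly modulates; ``a_shift=0`` gives a
    planted null.
    """
    if direction == ScanDirection.PI:
        base = BASELINE_H
    else:
        base = BASELINE_D
    shifted = AllometryParams(base.direction, base.h0, base.a + a_shift, base.b, base.d)
    return {"nn": base, "np": shifted}


def _segregate(rng: np.random.Generator, n: int, cross_type: CrossType) -> np.ndarray:
    if cross_type == CrossType.TESTCROSS:
        codes = np.array(["nn", "np"])
        return codes[rng.integers(0, 2, size=n)]
    codes = np.array(["aa", "ab", "bb"])
    return codes[rng.choice(3, size=n, p=[0.25, 0.5, 0.25])]


def _check_domain(params: AllometryParams, d_range: tuple[float, float]) -> None:
    lo, hi = d_range
    if params.direction == Direction.H_FROM_D:
        if params.b + lo <= 0:
            raise ValueError(
                f"causal parameters out of domain: b + D = {params.b + lo:g} <= 0 "
                f"over simulated diameter range [{lo:g}, {hi:g}]"
            )
    # D_FROM_H domain is checked against realised heights at generation time


def simulate_population(
    n: int = 180,
    T: int = 12,
    n_markers: int = 50,
    causal: list[CausalQtlSpec] | None = None,
    noise: AR1Params = AR1Params(rho=0.5, sigma2=1.0),
    seed: int = 0,
    diameter_noise: AR1Params = AR1Params(rho=0.5, sigma2=0.04),
    h0_mean: float = 20.0,
    family_id: str = "synthetic",
) -> MappingPopulation:
    """Generate a full-sib mapping population with optional planted QTLs.

    Parameters
    ----------
    n, T, n_markers
        Progeny count (>= 40), occasions (>= 5), marker count.
    causal
        Planted QTL specs; indices must be < ``n_markers``.  Non-causal
        markers segregate independently of phenotype.
    noise
        AR(1) residual of the generated response trait (height for a
        piQTL population, variance in cm^2).
    seed
        Single seed for all randomness.
    """
    if n < 40 or T < 5:
        raise ValueError("need n >= 40 individuals and T >= 5 occasions")
    causal = list(causal or [])
    for spec in causal:
        if not (0 <= spec.marker_index < n_markers):
            raise ValueError(f"causal marker index {spec.marker_index} out of range")
    rng = np.random.default_rng(seed)

    # logistic diameter growth (mm), biweekly occasions t = 1..T
    t = np.arange(1, T + 1, dtype=float)
    d_max = rng.normal(12.0, 1.2, size=n).clip(8.0, 16.0)
    rate = rng.normal(0.55, 0.06, size=n).clip(0.35, 0.8)
    t_mid = rng.normal(0.55 * T, 0.08 * T, size=n)
    diameters = d_max[:, None] / (1.0 + np.exp(-rate[:, None] * (t[None, :] - t_mid[:, None])))
    chol_dn = np.linalg.cholesky(ar1_matrix(diameter_noise, T))
    diameters = np.maximum(
        diameters + rng.standard_normal((n, T)) @ chol_dn.T, 0.05
    )
    d_range = (float(diameters.min()), float(diameters.max()))

    # genotype codes marker by marker
    cross_types = []
    codes_by_marker = []
    causal_by_index = {spec.marker_index: spec for spec in causal}
    for m in range(n_markers):
        if m in causal_by_index:
            ct = causal_by_index[m].cross_type
        else:
            ct = CrossType.TESTCROSS if rng.random() < 0.5 else CrossType.INTERCROSS
        cross_types.append(ct)
        codes_by_marker.append(_segregate(rng, n, ct))

    # height from diameter: genotype-specific parameters at the planted
    # piQTL (if any), baseline otherwise
    h0 = rng.normal(h0_mean, 2.0, size=n).clip(5.0, None)
    pi_specs = [s for s in causal if s.direction == ScanDirection.PI]
    if len(pi_specs) > 1:
        raise ValueError("at most one planted piQTL is supported")
    params_per_ind = np.tile(BASELINE_H.as_vector(), (n, 1))
    if pi_specs:
        spec = pi_specs[0]
        for code, params in spec.genotype_params.items():
            _check_domain(params, d_range)
            mask = codes_by_marker[spec.marker_index] == code
            params_per_ind[mask] = params.as_vector()
    mi_specs = [s for s in causal if s.direction == ScanDirection.MI]
    if len(mi_specs) > 1:
        raise ValueError("at most one planted miQTL is supported")

    a, b, d = params_per_ind.T
    mu_h = h0[:, None] + np.exp(a[:, None] + d[:, None] / (b[:, None] + diameters))
    # the response trait carries the configured AR(1) noise; the co-trait
    # gets its own (smaller) residual so it stays a clean predictor
    height_noise = noise if not mi_specs else AR1Params(rho=noise.rho, sigma2=0.09)
    chol_h = np.linalg.cholesky(ar1_matrix(height_noise, T))
    heights = mu_h + rng.standard_normal((n, T)) @ chol_h.T

    # planted miQTL: regenerate diameter from height through the reverse
    # equation; heights keep their mechanistic link to the original
    # logistic diameters plus noise
    if mi_specs:
        spec = mi_specs[0]
        params_mi = np.tile(BASELINE_D.as_vector(), (n, 1))
        for code, params in spec.genotype_params.items():
            mask = codes_by_marker[spec.marker_index] == code
            params_mi[mask] = params.as_vector()
        a, b, d = params_mi.T
        h0_obs = heights[:, 0]
        excess = heights - h0_obs[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = a[:, None] - np.log(excess)
            mu_d = d[:, None] / denom - b[:, None]
        if np.nanmin(denom) <= 0:
            raise ValueError("causal miQTL parameters out of domain over simulated heights")
        # cells where the height has not yet risen above the baseline carry
        # no scaling information; keep the mechanistic diameter there
        usable = np.isfinite(mu_d) & (excess > 0)
        chol_d = np.linalg.cholesky(ar1_matrix(noise, T))
        new_d = mu_d + rng.standard_normal((n, T)) @ chol_d.T
        diameters = np.where(usable, new_d, diameters)

    markers = [
        MarkerRecord(
            id=f"m{m + 1:04d}",
            chrom=f"chr{m % 8 + 1}",
            pos=100_000 * (m + 1),
            cross_type=cross_types[m],
            codes=list(codes_by_marker[m]),
        )
        for m in range(n_markers)
    ]
    return MappingPopulation(
        heights=heights, diameters=diameters, markers=markers, family_id=family_id
    )
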