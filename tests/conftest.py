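import numpy as np
import pytest

from allonet.covariance import AR1Params
from allonet.funmap import CrossType, ScanDirection
from allonet.synthpop import CausalQtlSpec, default_genotype_params, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """60 progeny, 8 occasions, 6 markers, one planted testcross piQTL at index 2."""
    causal = [CausalQtlSpec(2, CrossType.TESTCROSS, ScanDirection.PI,
                            default_genotype_params())]
    return simulate_population(n=60, T=8, n_markers=6, causal=causal,
                               noise=AR1Params(rho=0.5, sigma2=0.25), seed=11)


@pytest.fixture(scope="session")
def null_pop():
    """Population with no causal marker."""
    return simulate_population(n=60, T=8, n_markers=4, causal=None,
                               noise=AR1Params(rho=0.5, sigma2=0.25), seed=13)


@pytest.fixture(scope="session")
def effect_curve_trio():
    """Three smooth effect curves: A is driven by B (dA/dt = 0.3 B), C is independent."""
    from allonet.funmap import EffectCurve

    t = np.linspace(0.0, 10.0, 30)
    B = 3.0 / (1.0 + np.exp(-1.5 * (t - 4.0)))
    A = 1.0 + 0.3 * np.concatenate(
        [[0.0], np.cumsum(np.diff(t) * (B[:-1] + B[1:]) / 2.0)])
    C = 2.0 / (1.0 + np.exp(-2.0 * (t - 7.0)))
    return (
        EffectCurve("A", "piQTL", t, t, A),
        EffectCurve("B", "piQTL", t, t, B),
        EffectCurve("C", "piQTL", t, t, C),
    )
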