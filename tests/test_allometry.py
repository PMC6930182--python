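import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allonet.allometry import (
    AllometryDomainError,
    AllometryParams,
    Direction,
    compare_models_aic,
    fit_allometry,
    predict_d_from_h,
    predict_h_from_d,
)


class TestPrediction:
    def test_zero_rate_gives_constant_curve(self):
        p = AllometryParams(Direction.H_FROM_D, h0=20, a=3, b=1, d=0)
        out = predict_h_from_d(p, [1, 5, 50])
        assert np.allclose(out, 20 + math.e ** 3)

    def test_late_stage_asymptote_is_h0_plus_exp_a(self):
        p = AllometryParams(Direction.H_FROM_D, h0=20, a=3, b=1, d=-4)
        out = predict_h_from_d(p, [1e6])
        assert abs(out[0] - (20 + math.e ** 3)) < 1e-3

    def test_d_from_h_direct_substitution(self):
        p = AllometryParams(Direction.D_FROM_H, h0=0, a=2, b=1, d=4)
        assert predict_d_from_h(p, [math.e]) == pytest.approx([3.0])

    def test_negative_predicted_diameter_is_flagged(self):
        # as H -> h0+ the formula tends to -b; must raise, not return it
        p = AllometryParams(Direction.D_FROM_H, h0=0, a=2, b=1, d=4)
        with pytest.raises(AllometryDomainError):
            predict_d_from_h(p, [1e-30])

    def test_domain_errors_carry_offending_index(self):
        p = AllometryParams(Direction.H_FROM_D, h0=0, a=1, b=-2, d=1)
        with pytest.raises(AllometryDomainError) as err:
            predict_h_from_d(p, [5.0, 1.0])
        assert err.value.index == 1
        with pytest.raises(AllometryDomainError):
            predict_h_from_d(p, [np.nan, 5.0])

    def test_monotone_in_h_when_d_positive(self):
        p = AllometryParams(Direction.D_FROM_H, h0=0, a=3, b=0.5, d=4)
        h = np.linspace(2.0, 15.0, 40)
        d = predict_d_from_h(p, h)
        assert np.all(np.diff(d) >= 0)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    a=st.floats(0.5, 3.0),
    b=st.floats(0.2, 3.0),
    d=st.floats(0.5, 6.0),
    h0=st.floats(0.0, 30.0),
)
def test_inverse_consistency_on_parameter_grid(a, b, d, h0):
    """The two scaling directions are mutual inverses under d_HfromD = -d_DfromH."""
    p_dh = AllometryParams(Direction.D_FROM_H, h0=h0, a=a, b=b, d=d)
    p_hd = p_dh.inverse()
    diam = np.linspace(0.5, 10.0, 13)
    h = predict_h_from_d(p_hd, diam)
    back = predict_d_from_h(p_dh, h)
    assert np.max(np.abs(back - diam) / diam) < 1e-9


class TestFit:
    def test_noise_free_recovery(self):
        truth = AllometryParams(Direction.H_FROM_D, h0=20, a=3, b=2, d=-5)
        x = np.arange(1.0, 16.0)
        y = predict_h_from_d(truth, x)
        fit = fit_allometry(x, y, Direction.H_FROM_D, h0=20.0, seed=0)
        est = fit.params
        assert fit.rss < 1e-8
        for got, want in ((est.a, 3), (est.b, 2), (est.d, -5)):
            assert abs(got - want) / abs(want) < 1e-3

    def test_constant_response_degenerates_to_flat_curve(self):
        x = np.arange(1.0, 11.0)
        y = np.full_like(x, 25.0)
        fit = fit_allometry(x, y, Direction.H_FROM_D, h0=20.0, seed=0)
        assert fit.rss < 1e-6
        pred = predict_h_from_d(fit.params, x)
        assert np.allclose(pred, 25.0, atol=1e-3)

    def test_warm_start_never_degrades(self):
        truth = AllometryParams(Direction.H_FROM_D, h0=20, a=3, b=2, d=-5)
        x = np.arange(1.0, 16.0)
        rng = np.random.default_rng(0)
        y = predict_h_from_d(truth, x) + 0.1 * rng.standard_normal(x.size)
        fit = fit_allometry(x, y, Direction.H_FROM_D, init=truth, seed=0)
        init_rss = float(np.sum((y - predict_h_from_d(truth, x)) ** 2))
        assert fit.rss <= init_rss + 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_allometry([1, 2, 3], [1, 2, 3], Direction.H_FROM_D)


class TestModelComparison:
    def test_true_allometry_model_wins(self):
        truth = AllometryParams(Direction.H_FROM_D, h0=20, a=3, b=2, d=-5)
        x = np.arange(1.0, 16.0)
        rng = np.random.default_rng(1)
        wins = 0
        for rep in range(20):
            y = predict_h_from_d(truth, x) + 0.05 * rng.standard_normal(x.size)
            table = compare_models_aic(x, y, seed=rep)
            wins += table[0]["model"] == "allometry"
        assert wins >= 19

    def test_exact_line_prefers_linear_model(self):
        x = np.arange(1.0, 16.0)
        y = 2.0 + 0.5 * x
        table = compare_models_aic(x, y, seed=0)
        assert table[0]["model"] == "linear"

    def test_aic_formula_and_tie_break(self):
        x = np.arange(1.0, 16.0)
        y = 2.0 + 0.5 * x
        table = compare_models_aic(x, y, seed=0)
        for row in table:
            if math.isfinite(row["aic"]):
                n = len(x)
                assert row["aic"] == pytest.approx(
                    n * math.log(max(row["rss"], 1e-300) / n) + 2 * row["k"])
        aics = [r["aic"] for r in table]
        assert aics == sorted(aics)
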