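"""Regression families: recovery, selection, prediction, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from stripsense import calibration as cal
from stripsense.calibration import (
    CalibrationError,
    backward_stepwise_aic,
    fit_linear_sum,
    fit_multiple_rg,
    fit_polynomial_sq,
    predict_concentration,
    published_model,
    residual_diagnostics,
)
from stripsense.reference import PUBLISHED_COEFFICIENTS


def _channels(rng, n):
    return (
        rng.uniform(98, 193, n),
        rng.uniform(57, 193, n),
        rng.uniform(114, 179, n),
    )


def _poly_eval(r, g, b, coefs):
    return (
        coefs["b"]
        + coefs["r"] * r
        + coefs["g"] * g
        + coefs["b_chan"] * b
        + coefs["r2"] * r**2
        + coefs["g2"] * g**2
        + coefs["b2"] * b**2
    )


def test_linear_sum_noiseless_recovery(rng):
    c = PUBLISHED_COEFFICIENTS["linear_sum"]
    r, g, b = _channels(rng, 30)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": c["b"] + c["sum"] * (r + g + b)})
    m = fit_linear_sum(rows)
    assert m.coef["sum"] == pytest.approx(c["sum"], abs=1e-6)
    assert m.intercept == pytest.approx(c["b"], abs=1e-6)


def test_multiple_rg_noiseless_recovery(rng):
    c = PUBLISHED_COEFFICIENTS["multiple_rg"]
    r, g, b = _channels(rng, 30)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": c["b"] + c["r"] * r + c["g"] * g})
    m = fit_multiple_rg(rows)
    assert m.coef["r"] == pytest.approx(c["r"], abs=1e-6)
    assert m.coef["g"] == pytest.approx(c["g"], abs=1e-6)
    assert m.intercept == pytest.approx(c["b"], abs=1e-6)


def test_polynomial_noiseless_recovery(rng):
    c = PUBLISHED_COEFFICIENTS["polynomial_sq"]
    r, g, b = _channels(rng, 60)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": _poly_eval(r, g, b, c)})
    m = fit_polynomial_sq(rows)
    for term in m.terms:
        assert m.coef[term] == pytest.approx(c[term], abs=1e-5)
    assert m.intercept == pytest.approx(c["b"], abs=1e-5)


def test_rank_deficiency_errors(rng):
    n = 20
    const = np.full(n, 150.0)
    y = rng.normal(1.0, 0.1, n)
    with pytest.raises(CalibrationError):
        fit_linear_sum(pd.DataFrame({"r": const, "g": const, "b": const, "concentration": y}))
    r = rng.uniform(100, 200, n)
    with pytest.raises(CalibrationError):
        fit_multiple_rg(pd.DataFrame({"r": r, "g": r, "b": const, "concentration": y}))
    with pytest.raises(CalibrationError):
        fit_polynomial_sq(pd.DataFrame({"r": r, "g": r * 0 + 5, "b": const, "concentration": y}))


def test_two_point_exact_interpolation_flagged():
    rows = pd.DataFrame({"r": [100.0, 200.0], "g": [0.0, 0.0], "b": [0.0, 0.0], "concentration": [2.0, 1.0]})
    with pytest.warns(RuntimeWarning):
        m = fit_linear_sum(rows)
    assert np.isnan(m.adj_r2)
    assert np.allclose(m.residuals, 0.0, atol=1e-9)


def test_blue_insignificant_on_no_effect_data(rng):
    """With no true G effect, the G p-value is large on average over seeds."""
    ps = []
    for seed in range(30):
        local = np.random.default_rng(seed)
        r = local.uniform(98, 193, 40)
        g = local.uniform(57, 193, 40)
        y = 2.0 - 0.01 * r + local.normal(0, 0.1, 40)
        m = fit_multiple_rg(pd.DataFrame({"r": r, "g": g, "b": g * 0, "concentration": y}))
        ps.append(m.pvalues["g"])
    assert np.mean(ps) > 0.3


def test_stepwise_retains_full_model_and_drops_absent_terms(rng):
    c = PUBLISHED_COEFFICIENTS["polynomial_sq"]
    r, g, b = _channels(rng, 500)
    y_full = _poly_eval(r, g, b, c) + rng.normal(0, 0.02, 500)
    sel, trace = backward_stepwise_aic(pd.DataFrame({"r": r, "g": g, "b": b, "concentration": y_full}))
    assert set(sel.terms) == {"r", "g", "b_chan", "r2", "g2", "b2"}
    no_b = dict(c, b_chan=0.0, b2=0.0)
    y_nob = _poly_eval(r, g, b, no_b) + rng.normal(0, 0.02, 500)
    sel2, _ = backward_stepwise_aic(pd.DataFrame({"r": r, "g": g, "b": b, "concentration": y_nob}))
    assert "b_chan" not in sel2.terms and "b2" not in sel2.terms


def test_stepwise_aic_never_worse_than_full(rng):
    r, g, b = _channels(rng, 80)
    y = 3.0 - 0.005 * (r + g) + rng.normal(0, 0.3, 80)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": y})
    full = fit_polynomial_sq(rows)
    sel, _ = backward_stepwise_aic(rows)
    assert sel.aic <= full.aic + 1e-9


def test_stepwise_single_term_equals_simple_fit(rng):
    r, g, b = _channels(rng, 40)
    y = 1.0 + 0.01 * r + rng.normal(0, 0.05, 40)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": y})
    sel, trace = backward_stepwise_aic(rows, full_terms=("r",))
    simple = cal._fit_ols(rows, "polynomial_sq", ("r",))
    assert sel.terms == ("r",)
    assert sel.coef["r"] == pytest.approx(simple.coef["r"])
    assert trace == []


def test_predict_published_polynomial():
    model = published_model("polynomial_sq")
    # intercept only at the origin
    assert predict_concentration(model, (0, 0, 0)) == pytest.approx(10.86)
    # hand evaluation at (150, 60, 120)
    c = PUBLISHED_COEFFICIENTS["polynomial_sq"]
    expected = _poly_eval(np.array(150.0), np.array(60.0), np.array(120.0), c)
    assert predict_concentration(model, (150, 60, 120)) == pytest.approx(float(expected), rel=1e-12)


def test_predict_linear_sum_zero_crossing():
    """The channel sum that solves b + x*sum = 0 predicts exactly 0."""
    model = published_model("linear_sum")
    c = PUBLISHED_COEFFICIENTS["linear_sum"]
    s0 = -c["b"] / c["sum"]
    pred = model.intercept + model.coef["sum"] * s0
    assert pred == pytest.approx(0.0, abs=1e-9)


def test_predict_rejects_out_of_range():
    model = published_model()
    with pytest.raises(ValueError):
        predict_concentration(model, (300, 100, 100))


def test_fit_predict_residual_mean_zero(rng):
    """OLS normal equations force mean-zero training residuals."""
    r, g, b = _channels(rng, 50)
    y = 2.0 - 0.004 * (r + g + b) + rng.normal(0, 0.2, 50)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": y})
    for fit in (fit_linear_sum, fit_multiple_rg, fit_polynomial_sq):
        m = fit(rows)
        preds = [predict_concentration(m, (ri, gi, bi)) for ri, gi, bi in zip(r, g, b)]
        assert np.mean(y - np.array(preds)) == pytest.approx(0.0, abs=1e-9)


def test_residual_diagnostics_degenerate_and_shapes(rng):
    r, g, b = _channels(rng, 30)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": 1.0 + 0.01 * r})
    m = fit_polynomial_sq(rows)
    rep = residual_diagnostics(m)
    assert rep["degenerate"] is True and np.isnan(rep["shapiro_w"])


def test_residual_diagnostics_detects_u_shape(rng):
    """Strongly U-shaped residuals fail the Shapiro-Wilk normality test."""
    n = 200
    r = np.linspace(98, 193, n)
    g = rng.uniform(57, 193, n)
    b = rng.uniform(114, 179, n)
    y = 1.0 + 0.01 * r + 0.0008 * (r - 145) ** 2  # curvature the linear fit cannot absorb
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": y})
    m = fit_multiple_rg(rows)
    rep = residual_diagnostics(m)
    assert rep["shapiro_p"] < 0.05


def test_shapiro_type_I_rate_near_nominal():
    """On genuinely normal residuals the test rejects at ~5%."""
    rejections = 0
    reps = 200
    for seed in range(reps):
        local = np.random.default_rng(seed)
        r = local.uniform(98, 193, 97)
        g = local.uniform(57, 193, 97)
        y = 2.0 + 0.001 * r + local.normal(0, 0.1, 97)
        m = fit_multiple_rg(pd.DataFrame({"r": r, "g": g, "b": g * 0, "concentration": y}))
        if residual_diagnostics(m)["shapiro_p"] < 0.05:
            rejections += 1
    assert 0.01 <= rejections / reps <= 0.11


def test_model_json_round_trip(rng):
    r, g, b = _channels(rng, 30)
    rows = pd.DataFrame({"r": r, "g": g, "b": b, "concentration": 1 + 0.01 * r - 0.02 * g})
    m = fit_multiple_rg(rows)
    m2 = cal.FittedModel.from_json(m.to_json())
    assert m2.coef == pytest.approx(m.coef)
    assert predict_concentration(m2, (150, 120, 140)) == pytest.approx(
        predict_concentration(m, (150, 120, 140))
    )
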