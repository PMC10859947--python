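import numpy as np
import pytest

from bloodcast import (
    PanelError,
    SarimaForecaster,
    SarimaOrder,
    acf,
    acf_pacf,
    adf_test,
    decompose,
    pacf,
)

from conftest import make_panel
from _oracles import yule_walker_pacf


def ar1_series(seed, n=120, phi=0.7, mean=50.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal()
    return x + mean


# ------------------------------------------------------------------------- ADF
def test_adf_white_noise_stationary():
    rng = np.random.default_rng(1)
    report = adf_test(rng.normal(100, 5, 72))
    assert report.stationary
    assert report.p_value < 0.05


def test_adf_random_walk_not_stationary():
    rng = np.random.default_rng(2)
    walk = np.cumsum(rng.normal(size=72))
    assert not adf_test(walk).stationary


def test_adf_degenerate_inputs():
    with pytest.raises(PanelError, match="constant"):
        adf_test(np.full(72, 3.0))
    with pytest.raises(PanelError, match="24"):
        adf_test(np.arange(10.0))


# --------------------------------------------------------------- decomposition
def test_decompose_sine_recovery():
    t = np.arange(96)
    x = 100.0 + 5.0 * np.sin(2 * np.pi * t / 12)
    res = decompose(x, model="additive")
    inner = slice(6, 90)
    np.testing.assert_allclose(res.trend.to_numpy()[inner], 100.0, atol=1e-6)
    np.testing.assert_allclose(
        res.seasonal.to_numpy(), 5.0 * np.sin(2 * np.pi * t / 12), atol=1e-6
    )


def test_decompose_constant_additive():
    res = decompose(np.full(48, 7.0), model="additive")
    np.testing.assert_allclose(res.seasonal.to_numpy(), 0.0, atol=1e-12)
    valid = ~np.isnan(res.residual.to_numpy())
    np.testing.assert_allclose(res.residual.to_numpy()[valid], 0.0, atol=1e-12)


def test_decompose_linear_trend_no_seasonality():
    x = 10.0 + 0.5 * np.arange(60)
    res = decompose(x, model="additive")
    np.testing.assert_allclose(res.seasonal.to_numpy(), 0.0, atol=1e-9)


@pytest.mark.parametrize("model", ["additive", "multiplicative"])
def test_decompose_reconstruction_identity(model):
    rng = np.random.default_rng(3)
    panel = make_panel(
        "rec", {2017 + i: rng.uniform(50, 150, 12).tolist() for i in range(4)}
    )
    res = decompose(panel, model=model)
    obs = res.observed.to_numpy()
    if model == "additive":
        recon = res.trend + res.seasonal + res.residual
    else:
        recon = res.trend * res.seasonal * res.residual
    valid = ~np.isnan(res.trend.to_numpy())
    np.testing.assert_allclose(recon.to_numpy()[valid], obs[valid], rtol=1e-9)


def test_decompose_matches_statsmodels():
    from statsmodels.tsa.seasonal import seasonal_decompose

    rng = np.random.default_rng(4)
    x = rng.uniform(50, 150, 72)
    mine = decompose(x, model="additive")
    ref = seasonal_decompose(x, model="additive", period=12)
    np.testing.assert_allclose(mine.seasonal.to_numpy(), ref.seasonal, atol=1e-10)
    valid = ~np.isnan(ref.trend)
    np.testing.assert_allclose(
        mine.trend.to_numpy()[valid], ref.trend[valid], atol=1e-10
    )


def test_decompose_too_short():
    with pytest.raises(PanelError, match="24"):
        decompose(np.arange(20.0))


# -------------------------------------------------------------------- acf/pacf
def test_acf_lag0_and_ar1():
    x = ar1_series(5, n=500, phi=0.8)
    a = acf(x, 10)
    assert a[0] == 1.0
    assert abs(a[1] - 0.8) < 0.1


def test_acf_white_noise_bounds():
    rng = np.random.default_rng(6)
    w = rng.normal(size=400)
    a = acf(w, 40)
    frac_small = np.mean(np.abs(a[1:]) < 2 / np.sqrt(len(w)))
    assert frac_small >= 0.9


def test_pacf_matches_yule_walker_solve(rng):
    """Durbin–Levinson agrees with a direct Toeplitz solve of the
    Yule–Walker systems on random series."""
    for _ in range(20):
        x = rng.normal(size=rng.integers(60, 200))
        nlags = 15
        mine = pacf(x, nlags)
        ref = yule_walker_pacf(list(acf(x, nlags)))
        np.testing.assert_allclose(mine, ref, atol=1e-9)


def test_pacf_matches_statsmodels():
    import statsmodels.tsa.stattools as st

    x = ar1_series(7, n=240)
    np.testing.assert_allclose(
        pacf(x, 20)[1:], st.pacf(x, nlags=20, method="ywm")[1:], atol=1e-8
    )


def test_acf_pacf_constant_errors():
    with pytest.raises(PanelError, match="constant"):
        acf_pacf(np.full(60, 1.0), 10)
    with pytest.raises(ValueError, match="nlags"):
        acf(np.arange(20.0), 10)


# ----------------------------------------------------------------- order search
def test_sarima_order_validation():
    with pytest.raises(ValueError):
        SarimaOrder(-1, 0, 0)
    o = SarimaOrder(1, 0, 1, 0, 1, 1, 12)
    assert str(o) == "(1,0,1)(0,1,1)[12]"
    assert o.n_params == 1 + 1 + 0 + 1 + 0 + 1  # coefs + sigma2, no intercept (D=1)


def test_fixed_order_mean_model_forecasts_constant():
    rng = np.random.default_rng(8)
    x = rng.normal(80, 1, 72)
    est = SarimaForecaster(order=(0, 0, 0)).fit(x)
    fc = est.forecast(6)
    np.testing.assert_allclose(fc, np.full(6, x.mean()), rtol=0.01)
    assert (fc >= 0).all()


def test_ar1_forecast_closed_form_decay():
    x = ar1_series(9, n=200, phi=0.7, mean=50.0)
    est = SarimaForecaster(order=(1, 0, 0)).fit(x)
    phi = float(est.params_["ar.L1"])
    const = float(est.params_["intercept"])
    fc = est.forecast(12)
    # closed-form recursion y_{t+h} = const + phi * y_{t+h-1}
    prev = x[-1]
    for h in range(12):
        prev = const + phi * prev
        assert fc[h] == pytest.approx(prev, rel=1e-6)


def test_seasonal_signal_repeats():
    t = np.arange(96)
    x = 100.0 + 20.0 * np.sin(2 * np.pi * t / 12)
    est = SarimaForecaster(order=(0, 0, 0, 0, 1, 0)).fit(x)
    fc = est.forecast(12)
    np.testing.assert_allclose(fc, x[-12:], rtol=0.05)


def test_auto_search_min_aic_invariant():
    x = ar1_series(10, n=96)
    est = SarimaForecaster(max_p=1, max_q=1, max_d=1, max_P=0, max_D=0, max_Q=0).fit(x)
    ok = [c for c in est.candidates_ if c.converged and np.isfinite(c.aic)]
    assert ok, "no converged candidate"
    assert all(est.aic_ <= c.aic + 1e-9 for c in ok)
    assert est.aic_ == pytest.approx(2 * est.order_.n_params - 2 * est.loglik_, rel=1e-6)


def test_white_noise_prefers_parsimony():
    """On white noise, the minimum-AIC model carries at most one AR+MA
    parameter in at least 90% of seeded replicates."""
    wins = 0
    n_rep = 50
    for s in range(n_rep):
        rng = np.random.default_rng(1000 + s)
        w = rng.normal(10, 1, 80)
        est = SarimaForecaster(
            max_p=1, max_q=1, max_d=0, max_P=0, max_D=0, max_Q=0
        ).fit(w)
        if est.order_.p + est.order_.q <= 1:
            wins += 1
    assert wins / n_rep >= 0.9


def test_constant_series_rejected():
    with pytest.raises(PanelError, match="constant"):
        SarimaForecaster(order=(1, 0, 0)).fit(np.full(72, 5.0))


def test_predict_on_panel_gives_forecast_series(rng):
    panel = make_panel(
        "p", {2017 + i: (rng.uniform(80, 120, 12)).tolist() for i in range(5)}
    )
    est = SarimaForecaster(order=(1, 0, 0)).fit(panel)
    fc = est.predict()
    assert fc.target_year == 2022
    assert fc.values.shape == (12,)
    assert (fc.values >= 0).all()
    frame = est.report_frame()
    assert {"model", "aic", "bic"} <= set(frame["field"])
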