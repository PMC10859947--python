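"""Seasonal-ARIMA comparator: stationarity gate, decomposition, order search.

Coefficient estimation, the ADF regression machinery and likelihood
evaluation are delegated to statsmodels; this module owns the exhaustive
minimum-AIC order search, the classical moving-average decomposition, the
ACF/PACF diagnostics (Durbin–Levinson), and the reporting contract.

The model is the multiplicative seasonal ARIMA(p,d,q)(P,D,Q)s with s = 12
for monthly data. Candidate orders within the search bounds are each fitted
by maximum likelihood; the converged candidate with the smallest AIC wins,
ties broken by fewer estimated parameters, then lexicographically on
(p,d,q,P,D,Q).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tools.sm_exceptions import ConvergenceWarning
from statsmodels.tsa.stattools import adfuller
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .base import ForecastSeries, MonthlyForecaster, check_is_fitted
from .panel import MonthlyPanel, PanelError

__all__ = [
    "SarimaOrder",
    "StationarityReport",
    "DecompositionResult",
    "adf_test",
    "decompose",
    "acf",
    "pacf",
    "acf_pacf",
    "SarimaForecaster",
    "auto_sarima",
    "sarima_forecast",
]


# ------------------------------------------------------------------ stationarity
@dataclass(frozen=True)
class StationarityReport:
    """Augmented Dickey–Fuller unit-root test result.

    The null hypothesis is a unit root (non-stationarity); ``stationary`` is
    True when the p-value falls below ``alpha``.
    """

    statistic: float
    p_value: float
    n_lags: int
    n_obs: int
    stationary: bool
    alpha: float = 0.05


def _as_values(series) -> np.ndarray:
    if isinstance(series, MonthlyPanel):
        return series.data.to_numpy(dtype=float)
    return np.asarray(series, dtype=float).ravel()


def adf_test(series, alpha: float = 0.05) -> StationarityReport:
    """ADF unit-root test with AIC-selected lag order.

    Accepts a :class:`MonthlyPanel` or any ordered value sequence of at
    least 24 observations.
    """
    x = _as_values(series)
    if len(x) < 24:
        raise PanelError(f"ADF test needs >= 24 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise PanelError("ADF test undefined for a constant series")
    stat, pval, usedlag, nobs, _, _ = adfuller(x, autolag="AIC")
    return StationarityReport(
        statistic=float(stat),
        p_value=float(pval),
        n_lags=int(usedlag),
        n_obs=int(nobs),
        stationary=bool(pval < alpha),
        alpha=alpha,
    )


# ----------------------------------------------------------------- decomposition
@dataclass(frozen=True)
class DecompositionResult:
    """Classical decomposition into trend, seasonal and residual components.

    Additive: ``observed = trend + seasonal + residual`` wherever the
    centered moving-average trend is defined; multiplicative:
    ``observed = trend * seasonal * residual``.
    """

    observed: pd.Series
    trend: pd.Series
    seasonal: pd.Series
    residual: pd.Series
    model: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed,
                "trend": self.trend,
                "seasonal": self.seasonal,
                "residual": self.residual,
            }
        )


def decompose(panel, model: str = "additive", period: int = 12) -> DecompositionResult:
    """Classical seasonal decomposition with a centered 2x12 moving average.

    The trend is the 13-term centered filter (half weight at the ends) and is
    undefined at the first and last ``period//2`` points; the seasonal
    component is the month-wise mean of the detrended values, normalized to
    sum 0 (additive) or mean 1 (multiplicative); the residual is whatever is
    left.
    """
    if model not in ("additive", "multiplicative"):
        raise ValueError(f"unknown decomposition model {model!r}")
    if isinstance(panel, MonthlyPanel):
        observed = panel.to_monthly_series().astype(float)
        months = observed.index.month
    else:
        observed = pd.Series(np.asarray(panel, dtype=float))
        months = (np.arange(len(observed)) % period) + 1
    x = observed.to_numpy()
    n = len(x)
    if n < 2 * period:
        raise PanelError(f"decomposition needs >= {2 * period} observations, got {n}")
    if model == "multiplicative" and (x <= 0).any():
        raise PanelError("multiplicative decomposition requires positive values")

    half = period // 2
    filt = np.full(period + 1, 1.0 / period)
    filt[0] = filt[-1] = 0.5 / period
    trend = np.full(n, np.nan)
    trend[half : n - half] = np.convolve(x, filt, mode="valid")

    if model == "additive":
        detrended = x - trend
    else:
        detrended = x / trend

    month_means = np.empty(period)
    for m in range(1, period + 1):
        vals = detrended[(months == m) & ~np.isnan(detrended)]
        month_means[m - 1] = vals.mean() if len(vals) else np.nan
    if model == "additive":
        month_means -= np.nanmean(month_means)
    else:
        month_means /= np.nanmean(month_means)
    seasonal = month_means[np.asarray(months) - 1]

    if model == "additive":
        residual = x - trend - seasonal
    else:
        residual = x / (trend * seasonal)

    idx = observed.index
    return DecompositionResult(
        observed=observed,
        trend=pd.Series(trend, index=idx, name="trend"),
        seasonal=pd.Series(seasonal, index=idx, name="seasonal"),
        residual=pd.Series(residual, index=idx, name="residual"),
        model=model,
    )


# --------------------------------------------------------------------- acf/pacf
def acf(series, nlags: int) -> np.ndarray:
    """Standard sample autocorrelation function, lags 0..nlags.

    Uses the biased (1/n) covariance convention, which keeps the sample
    autocovariance sequence positive semi-definite.
    """
    x = _as_values(series)
    n = len(x)
    if nlags >= n / 2:
        raise ValueError(f"nlags={nlags} must be < n/2 = {n / 2}")
    if np.ptp(x) == 0:
        raise PanelError("ACF undefined for a constant series")
    xc = x - x.mean()
    denom = float(xc @ xc)
    out = np.empty(nlags + 1)
    out[0] = 1.0
    for k in range(1, nlags + 1):
        out[k] = float(xc[k:] @ xc[:-k]) / denom
    return out


def pacf(series, nlags: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin–Levinson recursion.

    Solves the Yule–Walker equations on the sample ACF recursively; entry 0
    is 1 by convention.
    """
    rho = acf(series, nlags)
    out = np.empty(nlags + 1)
    out[0] = 1.0
    if nlags == 0:
        return out
    phi_prev = np.array([rho[1]])
    out[1] = rho[1]
    for k in range(2, nlags + 1):
        num = rho[k] - float(phi_prev @ rho[k - 1 : 0 : -1])
        den = 1.0 - float(phi_prev @ rho[1:k])
        phi_kk = num / den
        phi = np.empty(k)
        phi[: k - 1] = phi_prev - phi_kk * phi_prev[::-1]
        phi[k - 1] = phi_kk
        out[k] = phi_kk
        phi_prev = phi
    return out


def acf_pacf(series, nlags: int) -> tuple[np.ndarray, np.ndarray]:
    """Both diagnostic sequences at once (order-identification aid)."""
    return acf(series, nlags), pacf(series, nlags)


# ----------------------------------------------------------------------- SARIMA
@dataclass(frozen=True, order=True)
class SarimaOrder:
    """Order tuple (p,d,q)(P,D,Q)s of a seasonal ARIMA model."""

    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    s: int = 12

    def __post_init__(self) -> None:
        for name in ("p", "d", "q", "P", "D", "Q", "s"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"order component {name} must be a non-negative integer")

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, self.s)

    @property
    def n_params(self) -> int:
        # AR/MA coefficients plus intercept (when no differencing) plus sigma2
        return self.p + self.q + self.P + self.Q + (1 if self.d + self.D == 0 else 0) + 1

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})[{self.s}]"


@dataclass(frozen=True)
class CandidateResult:
    order: SarimaOrder
    aic: float
    bic: float
    converged: bool
    error: str | None = None


class SarimaForecaster(MonthlyForecaster):
    """Seasonal ARIMA with exhaustive minimum-AIC order search.

    Parameters
    ----------
    order : SarimaOrder or tuple, optional
        Fix the order instead of searching. A 3-tuple means a non-seasonal
        model; a 6- or 7-tuple fills (p,d,q,P,D,Q[,s]).
    max_p, max_d, max_q, max_P, max_D, max_Q : int
        Search bounds (inclusive). Defaults give the conventional grid
        p,q <= 3, d <= 2, P,Q <= 2, D <= 1.
    s : int
        Seasonal period; 12 for monthly data.
    stepwise : bool
        If True, hill-climb from a handful of standard starting orders
        instead of the full grid (faster, possibly sub-optimal).
    trend : {"auto", "c", "n"}
        "auto" includes an intercept only for undifferenced models, the
        convention of the usual auto-ARIMA tools.

    Fitted attributes include ``order_``, ``aic_``, ``bic_``, ``loglik_``,
    ``params_`` / ``bse_`` (coefficient table), ``sigma2_``, ``candidates_``
    (every attempted order with its AIC), and ``results_`` (the underlying
    statsmodels results object).
    """

    method_name = "sarima"

    def __init__(
        self,
        order=None,
        max_p: int = 3,
        max_d: int = 2,
        max_q: int = 3,
        max_P: int = 2,
        max_D: int = 1,
        max_Q: int = 2,
        s: int = 12,
        stepwise: bool = False,
        trend: str = "auto",
        maxiter: int = 100,
    ):
        self.order = order
        self.max_p = max_p
        self.max_d = max_d
        self.max_q = max_q
        self.max_P = max_P
        self.max_D = max_D
        self.max_Q = max_Q
        self.s = s
        self.stepwise = stepwise
        self.trend = trend
        self.maxiter = maxiter

    # ------------------------------------------------------------------ fitting
    def _coerce_order(self, order) -> SarimaOrder:
        if isinstance(order, SarimaOrder):
            return order
        t = tuple(int(v) for v in order)
        if len(t) == 3:
            return SarimaOrder(*t, 0, 0, 0, self.s)
        if len(t) == 6:
            return SarimaOrder(*t, self.s)
        if len(t) == 7:
            return SarimaOrder(*t)
        raise ValueError(f"cannot interpret order {order!r}")

    def _trend_for(self, order: SarimaOrder) -> str:
        if self.trend == "auto":
            return "c" if order.d + order.D == 0 else "n"
        return self.trend

    def _fit_one(self, y: pd.Series, order: SarimaOrder):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            warnings.simplefilter("ignore", category=UserWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            model = SARIMAX(
                y,
                order=order.order,
                seasonal_order=order.seasonal_order if order.s > 0 else (0, 0, 0, 0),
                trend=self._trend_for(order),
            )
            res = model.fit(disp=False, maxiter=self.maxiter)
        converged = bool(res.mle_retvals.get("converged", True))
        if not np.isfinite(res.aic):
            raise FloatingPointError("non-finite AIC")
        return res, converged

    def _grid(self):
        return [
            SarimaOrder(p, d, q, P, D, Q, self.s)
            for p, d, q, P, D, Q in itertools.product(
                range(self.max_p + 1),
                range(self.max_d + 1),
                range(self.max_q + 1),
                range(self.max_P + 1),
                range(self.max_D + 1),
                range(self.max_Q + 1),
            )
        ]

    def _stepwise_orders(self):
        seeds = [
            SarimaOrder(0, 0, 0, 0, 0, 0, self.s),
            SarimaOrder(1, 0, 0, 0, 0, 0, self.s),
            SarimaOrder(0, 0, 1, 0, 0, 0, self.s),
            SarimaOrder(1, 0, 1, 1, 0, 1, self.s),
            SarimaOrder(2, 1, 2, 1, 0, 1, self.s),
        ]
        bounds = (self.max_p, self.max_d, self.max_q, self.max_P, self.max_D, self.max_Q)
        return [
            o
            for o in seeds
            if all(v <= b for v, b in zip((o.p, o.d, o.q, o.P, o.D, o.Q), bounds))
        ]

    def _neighbours(self, o: SarimaOrder):
        bounds = {
            "p": self.max_p, "d": self.max_d, "q": self.max_q,
            "P": self.max_P, "D": self.max_D, "Q": self.max_Q,
        }
        for name, bound in bounds.items():
            for delta in (-1, 1):
                v = getattr(o, name) + delta
                if 0 <= v <= bound:
                    kw = {k: getattr(o, k) for k in ("p", "d", "q", "P", "D", "Q")}
                    kw[name] = v
                    yield SarimaOrder(s=self.s, **kw)

    def fit(self, panel, y=None) -> "SarimaForecaster":
        if isinstance(panel, MonthlyPanel):
            series = panel.to_monthly_series()
            self.label_ = panel.label
        else:
            series = pd.Series(np.asarray(panel, dtype=float))
            self.label_ = getattr(panel, "name", "") or ""
        if np.ptp(series.to_numpy()) == 0:
            raise PanelError("SARIMA undefined for a constant series")
        self._y = series

        if self.order is not None:
            chosen = self._coerce_order(self.order)
            res, converged = self._fit_one(series, chosen)
            self.candidates_ = [
                CandidateResult(chosen, float(res.aic), float(res.bic), converged)
            ]
            self._install(chosen, res)
            return self

        candidates: dict[SarimaOrder, CandidateResult] = {}
        fits: dict[SarimaOrder, object] = {}

        def try_order(o: SarimaOrder) -> float:
            if o in candidates:
                c = candidates[o]
                return c.aic if c.converged else np.inf
            try:
                res, converged = self._fit_one(series, o)
            except Exception as exc:  # noqa: BLE001 — candidate failure is data
                candidates[o] = CandidateResult(o, np.inf, np.inf, False, str(exc))
                return np.inf
            candidates[o] = CandidateResult(o, float(res.aic), float(res.bic), converged)
            if converged:
                fits[o] = res
                return float(res.aic)
            return np.inf

        if self.stepwise:
            for seed in self._stepwise_orders():
                aic = try_order(seed)
                current, best = seed, aic
                improved = True
                while improved and np.isfinite(best):
                    improved = False
                    for nb in self._neighbours(current):
                        a = try_order(nb)
                        if a < best - 1e-9:
                            current, best = nb, a
                            improved = True
        else:
            for o in self._grid():
                try_order(o)

        ok = [c for c in candidates.values() if c.converged and np.isfinite(c.aic)]
        if not ok:
            attempts = ", ".join(
                f"{c.order}: {c.error or 'did not converge'}" for c in candidates.values()
            )
            raise PanelError(f"no SARIMA candidate converged; attempts: {attempts}")
        # min AIC; ties -> fewer parameters -> lexicographic order
        best = min(ok, key=lambda c: (c.aic, c.order.n_params, c.order))
        self.candidates_ = sorted(candidates.values(), key=lambda c: c.order)
        self._install(best.order, fits[best.order])
        return self

    def _install(self, order: SarimaOrder, res) -> None:
        self.order_ = order
        self.results_ = res
        self.aic_ = float(res.aic)
        self.bic_ = float(res.bic)
        self.loglik_ = float(res.llf)
        self.params_ = res.params
        self.bse_ = res.bse
        self.sigma2_ = float(res.params.get("sigma2", np.nan))
        idx = self._y.index
        if isinstance(idx, pd.PeriodIndex):
            self.last_complete_year_ = (
                idx[-1].year if idx[-1].month == 12 else idx[-1].year - 1
            )
        else:
            self.last_complete_year_ = len(self._y) // 12
        fc = np.asarray(res.get_forecast(steps=12).predicted_mean, dtype=float)
        slope = float(np.polyfit(np.arange(12.0), fc, 1)[0])
        self.trend_direction_ = (
            "increase" if slope > 0 else "decrease" if slope < 0 else "flat"
        )

    # -------------------------------------------------------------- forecasting
    def forecast(self, horizon: int = 12) -> np.ndarray:
        """Point forecasts for the next *horizon* months, floored at 0."""
        check_is_fitted(self, "results_")
        fc = np.asarray(self.results_.get_forecast(steps=horizon).predicted_mean)
        return np.maximum(fc, 0.0)

    def predict(self, target_year: int | None = None) -> ForecastSeries:
        check_is_fitted(self, "results_")
        year = self._target_year(target_year)
        steps = 12 * (year - self.last_complete_year_)
        if steps < 12:
            raise ValueError(
                f"target year {year} is not after the last complete training year"
            )
        values = self.forecast(steps)[-12:]
        return ForecastSeries(self.method_name, year, values, label=self.label_)

    # ---------------------------------------------------------------- reporting
    def report_frame(self) -> pd.DataFrame:
        """Coefficient-table mirror: coef ± std err plus fit statistics."""
        check_is_fitted(self, "results_")
        rows = [
            {"field": "model", "value": str(self.order_), "std_err": None},
            {"field": "aic", "value": self.aic_, "std_err": None},
            {"field": "bic", "value": self.bic_, "std_err": None},
        ]
        for name in self.params_.index:
            rows.append(
                {
                    "field": name,
                    "value": float(self.params_[name]),
                    "std_err": float(self.bse_[name]),
                }
            )
        return pd.DataFrame(rows)


# ------------------------------------------------------------ functional facade
def auto_sarima(panel, **search_kwargs) -> SarimaForecaster:
    """Grid-search a SARIMA fit on *panel*; bounds forwarded to the estimator."""
    return SarimaForecaster(**search_kwargs).fit(panel)


def sarima_forecast(fit: SarimaForecaster, horizon: int = 12) -> np.ndarray:
    """Point forecasts from a fitted model, floored at zero."""
    return fit.forecast(horizon)
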