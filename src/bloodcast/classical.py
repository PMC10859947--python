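"""Classical comparator methods: simple average and ratio-to-trend.

Simple average is SAMAI without the growth scalar: the forecast for every
future year is just the per-month historical average, so it assumes no trend.

Ratio-to-trend is the classical decomposition recipe for monthly data with a
linear trend and multiplicative seasonality:

1.  fit, by ordinary least squares, a straight line to the yearly averages
    ``T[y]/12`` against the year index centered at the training midpoint
    (the line's value is the trend at each year's midpoint);
2.  interpolate the annual line to months — month ``m`` of a year sits
    ``(m - 6.5)/12`` of a year away from the year's midpoint, so
    ``t[y][m] = a + b*(y - origin) + (b/12)*(m - 6.5)``; this placement
    reproduces any series that is exactly linear in serial month index;
3.  express every training cell as a percentage of its trend value,
    ``ratio = 100 * X / t``;
4.  average the ratios month-wise;
5.  rescale by the correction factor ``1200 / sum(month averages)`` so the
    seasonal indices average exactly 100.

The forecast recombines trend and season, ``F[m] = t[Y][m] * SI[m] / 100``,
floored at zero when a falling trend extrapolates below it (demand counts
cannot be negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import ForecastSeries, MonthlyForecaster, check_is_fitted
from .panel import MONTHS, MonthlyPanel, PanelError
from .samai import _monthly_averages

__all__ = [
    "TrendFit",
    "RatioToTrendModel",
    "SimpleAverageForecaster",
    "RatioToTrendForecaster",
    "simple_average_forecast",
    "fit_annual_trend",
    "monthly_trend_values",
    "ratio_to_trend_model",
    "ratio_to_trend_forecast",
]


class SimpleAverageForecaster(MonthlyForecaster):
    """Forecast each month by its historical average (no trend, no growth).

    Shares the seasonal profile with SAMAI (``monthly_avg_``, ``grand_avg_``,
    ``seasonal_index_``); equals SAMAI exactly whenever R = 1.
    """

    method_name = "simple_average"

    def fit(self, panel: MonthlyPanel, y=None) -> "SimpleAverageForecaster":
        self.monthly_avg_ = _monthly_averages(panel)
        self.grand_avg_ = float(self.monthly_avg_.mean())
        if self.grand_avg_ == 0:
            raise PanelError("grand average is zero; seasonal indices undefined")
        self.seasonal_index_ = 100.0 * self.monthly_avg_ / self.grand_avg_
        self.last_complete_year_ = (panel.complete_years or panel.years)[-1]
        self.trend_direction_ = "flat"  # the method assumes no trend
        self.label_ = panel.label
        return self

    def predict(self, target_year: int | None = None) -> ForecastSeries:
        check_is_fitted(self, "monthly_avg_")
        year = self._target_year(target_year)
        return ForecastSeries(self.method_name, year, self.monthly_avg_.copy(),
                              label=self.label_)


@dataclass(frozen=True)
class TrendFit:
    """Least-squares line through yearly averages.

    ``intercept`` is the trend value (units/month) at ``origin``, the
    arithmetic midpoint of the training years; ``slope`` is in units/month
    per year.
    """

    intercept: float
    slope: float
    origin: float


@dataclass(frozen=True)
class RatioToTrendModel:
    trend: TrendFit
    seasonal_index: np.ndarray
    correction_factor: float


def fit_annual_trend(panel: MonthlyPanel) -> TrendFit:
    """OLS of yearly averages on the year index centered at the training midpoint."""
    years = panel.complete_years
    if len(years) < 2:
        raise PanelError(f"trend fit needs >= 2 complete years, got {len(years)}")
    x = np.asarray(years, dtype=float)
    yavg = np.array([panel.year_total(y) / 12.0 for y in years])
    origin = x.mean()
    xc = x - origin
    slope = float(xc @ yavg / (xc @ xc))
    intercept = float(yavg.mean())
    return TrendFit(intercept, slope, origin)


def monthly_trend_values(fit: TrendFit, year: int) -> np.ndarray:
    """Trend interpolated to the 12 month-midpoints of *year*."""
    m = np.arange(1, 13, dtype=float)
    return fit.intercept + fit.slope * (year - fit.origin) + fit.slope / 12.0 * (m - 6.5)


class RatioToTrendForecaster(MonthlyForecaster):
    """Classical ratio-to-trend decomposition forecaster.

    Fitted attributes
    -----------------
    trend_ : TrendFit
        Annual least-squares trend (intercept at the midpoint origin, slope
        per year).
    seasonal_index_ : ndarray (12,)
        Corrected seasonal indices, mean exactly 100.
    correction_factor_ : float
        ``1200 / sum(raw month-average ratios)``.
    trend_direction_ : str
        Sign of the fitted slope.
    """

    method_name = "ratio_to_trend"

    def fit(self, panel: MonthlyPanel, y=None) -> "RatioToTrendForecaster":
        self.trend_ = fit_annual_trend(panel)
        years = panel.complete_years
        ratios = np.empty((len(years), 12))
        for i, year in enumerate(years):
            t = monthly_trend_values(self.trend_, year)
            if (t <= 0).any():
                m = int(np.argmax(t <= 0)) + 1
                raise PanelError(
                    f"non-positive trend value at (year={year}, month={m}); "
                    "ratios undefined"
                )
            ratios[i] = 100.0 * panel.year_values(year) / t
        month_avg = ratios.mean(axis=0)
        self.correction_factor_ = 1200.0 / month_avg.sum()
        self.seasonal_index_ = month_avg * self.correction_factor_
        b = self.trend_.slope
        self.trend_direction_ = "increase" if b > 0 else "decrease" if b < 0 else "flat"
        self.last_complete_year_ = years[-1]
        self.label_ = panel.label
        return self

    def predict(self, target_year: int | None = None) -> ForecastSeries:
        check_is_fitted(self, "trend_")
        year = self._target_year(target_year)
        t = monthly_trend_values(self.trend_, year)
        values = np.maximum(t * self.seasonal_index_ / 100.0, 0.0)
        return ForecastSeries(self.method_name, year, values, label=self.label_)


# ------------------------------------------------------------ functional facade
def simple_average_forecast(panel: MonthlyPanel, target_year: int | None = None) -> ForecastSeries:
    return SimpleAverageForecaster().fit(panel).predict(target_year)


def ratio_to_trend_model(panel: MonthlyPanel) -> RatioToTrendModel:
    est = RatioToTrendForecaster().fit(panel)
    return RatioToTrendModel(est.trend_, est.seasonal_index_, est.correction_factor_)


def ratio_to_trend_forecast(panel: MonthlyPanel, target_year: int | None = None) -> ForecastSeries:
    return RatioToTrendForecaster().fit(panel).predict(target_year)
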