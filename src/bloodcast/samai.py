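"""SAMAI — simple average with mean annual increment.

The method assumes multiplicative seasonality and a steady geometric trend,
and deliberately needs nothing beyond arithmetic:

1.  arrange the data year-wise by calendar month;
2.  average each month across years -> monthly averages ``A[m]``;
3.  grand average ``G = (1/12) * sum(A)``;
4.  seasonal index ``SI[m] = 100 * A[m] / G`` (a flat series has SI = 100);
5–8. annual totals ``T[y]`` over complete years, year-over-year increment
    ratios ``r[y] = T[y] / T[y-1]``, and their mean ``R``;
9.  next-year forecast ``F[m] = A[m] * R``.

``R > 1`` reads as growth; setting ``R = 1`` recovers the plain
simple-average forecast. Forecasts ``k`` years past the next year scale as
``A[m] * R^k`` (an extension — the method itself defines only next-year
prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import ForecastSeries, MonthlyForecaster, check_is_fitted
from .panel import MONTHS, MonthlyPanel, PanelError

__all__ = [
    "SeasonalProfile",
    "IncrementSummary",
    "SamaiForecaster",
    "seasonal_profile",
    "increment_summary",
    "samai_forecast",
]


@dataclass(frozen=True)
class SeasonalProfile:
    """Monthly averages, grand average and seasonal indices of a panel.

    ``monthly_avg[m-1]`` is in units/month; ``seasonal_index`` is in percent
    of the grand average and averages exactly 100.
    """

    monthly_avg: np.ndarray
    grand_avg: float
    seasonal_index: np.ndarray


@dataclass(frozen=True)
class IncrementSummary:
    """Annual totals, consecutive-year ratios and their mean R."""

    years: tuple[int, ...]
    annual_total: np.ndarray
    increment_ratio: np.ndarray
    mean_increment: float


def _monthly_averages(panel: MonthlyPanel) -> np.ndarray:
    avgs = np.empty(12)
    for m in MONTHS:
        vals = panel.month_values(m)
        if len(vals) == 0:
            raise PanelError(f"no observations for calendar month {m}")
        avgs[m - 1] = vals.mean()
    return avgs


class SamaiForecaster(MonthlyForecaster):
    """Forecast next-year monthly demand by monthly averages scaled with the
    mean annual increment ratio.

    Fitted attributes
    -----------------
    monthly_avg_ : ndarray (12,)
        Mean of each calendar month across the training years; a partial
        tail year contributes to the months it covers.
    grand_avg_ : float
        Mean of the 12 monthly averages.
    seasonal_index_ : ndarray (12,)
        ``100 * monthly_avg_ / grand_avg_``; averages 100.
    annual_total_ : ndarray
        Totals of the complete training years (partial tail excluded).
    increment_ratio_ : ndarray
        ``T[y] / T[y-1]`` for consecutive complete years.
    mean_increment_ : float
        R, the mean of the increment ratios.
    trend_direction_ : str
        "increase" if R > 1, "decrease" if R < 1, "flat" at exactly 1.
    """

    method_name = "samai"

    def fit(self, panel: MonthlyPanel, y=None) -> "SamaiForecaster":
        complete = panel.complete_years
        if len(complete) < 2:
            raise PanelError(
                f"SAMAI needs >= 2 complete years, panel has {len(complete)}"
            )
        self.monthly_avg_ = _monthly_averages(panel)
        self.grand_avg_ = float(self.monthly_avg_.mean())
        if self.grand_avg_ == 0:
            raise PanelError("grand average is zero; seasonal indices undefined")
        self.seasonal_index_ = 100.0 * self.monthly_avg_ / self.grand_avg_

        totals = np.array([panel.year_total(y) for y in complete])
        if (totals <= 0).any():
            bad = complete[int(np.argmax(totals <= 0))]
            raise PanelError(f"annual total of year {bad} is not positive")
        self.years_ = tuple(complete)
        self.annual_total_ = totals
        self.increment_ratio_ = totals[1:] / totals[:-1]
        self.mean_increment_ = float(self.increment_ratio_.mean())
        self.last_complete_year_ = complete[-1]
        r = self.mean_increment_
        self.trend_direction_ = "increase" if r > 1 else "decrease" if r < 1 else "flat"
        self.label_ = panel.label
        return self

    def predict(self, target_year: int | None = None) -> ForecastSeries:
        check_is_fitted(self, "mean_increment_")
        year = self._target_year(target_year)
        k = year - self.last_complete_year_
        if k < 1:
            raise ValueError(
                f"target year {year} is not after the last complete training "
                f"year {self.last_complete_year_}"
            )
        values = self.monthly_avg_ * self.mean_increment_ ** k
        return ForecastSeries(self.method_name, year, values, label=self.label_)


# ------------------------------------------------------------ functional facade
def seasonal_profile(panel: MonthlyPanel) -> SeasonalProfile:
    """Monthly averages, grand average and seasonal indices of *panel*."""
    avgs = _monthly_averages(panel)
    grand = float(avgs.mean())
    if grand == 0:
        raise PanelError("grand average is zero; seasonal indices undefined")
    return SeasonalProfile(avgs, grand, 100.0 * avgs / grand)


def increment_summary(panel: MonthlyPanel) -> IncrementSummary:
    """Annual totals of complete years, consecutive ratios, and their mean R."""
    est = SamaiForecaster().fit(panel)
    return IncrementSummary(
        est.years_, est.annual_total_, est.increment_ratio_, est.mean_increment_
    )


def samai_forecast(panel: MonthlyPanel, target_year: int | None = None) -> ForecastSeries:
    """Fit SAMAI on *panel* and forecast *target_year* (default: next year)."""
    return SamaiForecaster().fit(panel).predict(target_year)
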