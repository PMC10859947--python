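"""Shared forecaster machinery: the estimator base class and forecast container."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .panel import MONTHS, MonthlyPanel

__all__ = ["ForecastSeries", "MonthlyForecaster", "check_is_fitted"]


@dataclass(frozen=True)
class ForecastSeries:
    """Twelve monthly point forecasts for one calendar year.

    ``values[m-1]`` is the forecast for month ``m``; all entries are
    non-negative by construction of every method in this package.
    """

    method: str
    target_year: int
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (12,):
            raise ValueError(f"forecast must have exactly 12 entries, got {vals.shape}")
        if (vals < 0).any():
            raise ValueError("forecast values must be non-negative")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, month: int) -> float:
        if not 1 <= month <= 12:
            raise IndexError(f"month {month} out of range 1..12")
        return float(self.values[month - 1])

    def head(self, k: int) -> np.ndarray:
        """Forecasts for months 1..k (aligning with a partial test year)."""
        return self.values[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": list(MONTHS), "value": self.values})

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def check_is_fitted(estimator: BaseEstimator, attr: str) -> None:
    if not hasattr(estimator, attr):
        raise NotFittedError(
            f"{type(estimator).__name__} is not fitted yet; call fit(panel) first"
        )


class MonthlyForecaster(BaseEstimator):
    """Base class for the seasonal demand forecasters.

    Subclasses implement ``fit(panel)`` setting trailing-underscore attributes
    and ``predict(target_year)`` returning a :class:`ForecastSeries`. They also
    expose ``trend_direction_`` after fitting ("increase" / "decrease" /
    "flat"), the growth classification reported alongside MAPE in the method
    comparison table.
    """

    method_name: str = "base"

    def fit(self, panel: MonthlyPanel, y=None) -> "MonthlyForecaster":  # pragma: no cover
        raise NotImplementedError

    def predict(self, target_year: int | None = None) -> ForecastSeries:  # pragma: no cover
        raise NotImplementedError

    def _target_year(self, target_year: int | None) -> int:
        check_is_fitted(self, "last_complete_year_")
        if target_year is None:
            return self.last_complete_year_ + 1
        return int(target_year)
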