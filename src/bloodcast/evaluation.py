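"""Forecast evaluation: MAPE scoring and multi-method comparison tables.

The comparison grid mirrors the standard reporting layout of this problem:
one row per (series, data-set variant), one column block per method, with
MAPE on the held-out months and the method's growth classification, plus
averaged rows per variant and combined. Averages are arithmetic means of the
constituent per-series MAPEs (the combined row averages all per-series
values, not the two variant averages — identical only when variant counts
match).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .base import MonthlyForecaster
from .classical import RatioToTrendForecaster, SimpleAverageForecaster
from .panel import MonthlyPanel
from .samai import SamaiForecaster
from .sarima import SarimaForecaster

__all__ = [
    "mape",
    "trend_direction",
    "ForecastScore",
    "ComparisonTable",
    "compare_methods",
    "METHOD_REGISTRY",
]


def mape(actual, forecast) -> float:
    """Mean absolute percentage error, ``(100/n) * sum(|A_t - F_t| / A_t)``.

    Zero actuals are an error (the term is undefined), reported with the
    offending index; demand counts in this domain are positive.
    """
    a = np.asarray(actual, dtype=float).ravel()
    f = np.asarray(forecast, dtype=float).ravel()
    if a.shape != f.shape:
        raise ValueError(f"length mismatch: actual {a.shape} vs forecast {f.shape}")
    if len(a) == 0:
        raise ValueError("MAPE needs at least one observation")
    zeros = np.flatnonzero(a == 0)
    if len(zeros):
        raise ValueError(f"MAPE undefined: actual value is zero at index {zeros[0]}")
    return float(100.0 * np.mean(np.abs(a - f) / np.abs(a)))


def trend_direction(model) -> str:
    """Growth classification of a fitted forecaster.

    SAMAI: increase iff R > 1. Ratio-to-trend / SARIMA: sign of the fitted
    (or forecast-horizon) slope. Exact zero reports "flat".
    """
    if hasattr(model, "trend_direction_"):
        return model.trend_direction_
    if hasattr(model, "mean_increment_"):
        r = model.mean_increment_
        return "increase" if r > 1 else "decrease" if r < 1 else "flat"
    raise TypeError(f"{type(model).__name__} exposes no growth measure")


METHOD_REGISTRY: dict[str, Callable[[], MonthlyForecaster]] = {
    "samai": SamaiForecaster,
    "simple_average": SimpleAverageForecaster,
    "ratio_to_trend": RatioToTrendForecaster,
    "sarima": SarimaForecaster,
}


@dataclass(frozen=True)
class ForecastScore:
    method: str
    series: str
    variant: str
    mape: float
    trend: str = ""
    growth: float | None = None  # SAMAI's R where applicable
    error: str | None = None

    def __post_init__(self) -> None:
        if self.error is None and self.mape < 0:
            raise ValueError("MAPE cannot be negative")


@dataclass
class ComparisonTable:
    """Per-method, per-series MAPE grid with averaged rows."""

    scores: list[ForecastScore]
    test_months: int = 0
    test_year: int | None = None
    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------------- views
    def grid(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "series": s.series,
                    "variant": s.variant,
                    "method": s.method,
                    "mape": s.mape,
                    "trend": s.trend,
                    "growth": s.growth,
                    "error": s.error,
                }
                for s in self.scores
            ]
        )

    def _ok(self) -> list[ForecastScore]:
        return [s for s in self.scores if s.error is None]

    def average(self, method: str, variant: str | None = None) -> float:
        """Mean MAPE of a method over per-series scores (one variant or all)."""
        vals = [
            s.mape
            for s in self._ok()
            if s.method == method and (variant is None or s.variant == variant)
        ]
        if not vals:
            raise ValueError(f"no scores for method={method!r}, variant={variant!r}")
        return float(np.mean(vals))

    def averages(self) -> pd.DataFrame:
        """Averaged rows: per method x (variant I, variant II, combined)."""
        methods = list(dict.fromkeys(s.method for s in self.scores))
        variants = list(dict.fromkeys(s.variant for s in self.scores))
        rows = []

        def _avg(method, variant=None):
            try:
                return self.average(method, variant)
            except ValueError:  # every cell failed for this method
                return np.nan

        for method in methods:
            row = {"method": method}
            for v in variants:
                row[f"avg_mape_{v}"] = _avg(method, v)
            row["avg_mape_combined"] = _avg(method)
            rows.append(row)
        return pd.DataFrame(rows)

    # --------------------------------------------------------------- rendering
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.grid().to_csv(path, index=False)
        return path

    def to_text(self) -> str:
        wide = self.grid().pivot_table(
            index=["series", "variant"], columns="method", values="mape"
        )
        lines = [
            f"Forecast comparison (MAPE %, test: {self.test_months} months"
            + (f" of {self.test_year})" if self.test_year else ")"),
            wide.round(2).to_string(),
            "",
            "Averaged rows:",
            self.averages().round(2).to_string(index=False),
        ]
        failed = [s for s in self.scores if s.error is not None]
        if failed:
            lines.append("")
            lines.append("Failed cells (excluded from averages):")
            for s in failed:
                lines.append(f"  {s.method} / {s.series} / {s.variant}: {s.error}")
        return "\n".join(lines)


def _resolve_method(method) -> tuple[str, Callable[[], MonthlyForecaster]]:
    if isinstance(method, str):
        if method not in METHOD_REGISTRY:
            raise ValueError(
                f"unknown method {method!r}; registered: {sorted(METHOD_REGISTRY)}"
            )
        return method, METHOD_REGISTRY[method]
    if isinstance(method, tuple):
        return method
    # an estimator factory / class with its own method_name
    name = getattr(method, "method_name", None) or method.__name__
    return name, method


def compare_methods(
    panels: Mapping[tuple[str, str], tuple[MonthlyPanel, MonthlyPanel]],
    methods: Sequence = ("samai", "simple_average", "ratio_to_trend", "sarima"),
    method_params: Mapping[str, dict] | None = None,
) -> ComparisonTable:
    """Fit every method on every (series, variant) train panel and score MAPE
    on the matching test panel.

    Parameters
    ----------
    panels : mapping ``(series_label, variant) -> (train, test)``
        Variants are free tags (conventionally "I" for actual data and "II"
        for the pandemic-imputed variant). Every test panel must cover the
        same window: a single (possibly partial) calendar year.
    methods : sequence of registry names, ``(name, factory)`` pairs, or
        estimator factories.
    method_params : per-method constructor keyword overrides, by name.

    Failed cells are recorded with their error and excluded from averages
    with a warning.
    """
    method_params = method_params or {}
    keys = list(panels)
    if not keys:
        raise ValueError("no panels supplied")

    windows = set()
    for train, test in panels.values():
        months = test.data.index.get_level_values("month")
        windows.add((test.years[0], int(months.min()), int(months.max())))
    if len(windows) > 1:
        raise ValueError(f"inconsistent test windows across series: {sorted(windows)}")
    test_year, m_lo, m_hi = windows.pop()
    if m_lo != 1:
        raise ValueError("test panels must start in January")
    n_test = m_hi

    scores: list[ForecastScore] = []
    for method in methods:
        name, factory = _resolve_method(method)
        for (label, variant), (train, test) in panels.items():
            try:
                est = factory(**method_params.get(name, {}))
                est.fit(train)
                forecast = est.predict(test_year)
                actual = test.data.to_numpy()
                score = mape(actual, forecast.head(n_test))
                scores.append(
                    ForecastScore(
                        method=name,
                        series=label,
                        variant=variant,
                        mape=score,
                        trend=trend_direction(est),
                        growth=getattr(est, "mean_increment_", None),
                    )
                )
            except Exception as exc:  # noqa: BLE001 — per-cell failure is data
                warnings.warn(
                    f"method {name} failed on ({label}, {variant}): {exc}",
                    stacklevel=2,
                )
                scores.append(
                    ForecastScore(
                        method=name, series=label, variant=variant,
                        mape=np.nan, error=str(exc),
                    )
                )
    return ComparisonTable(scores=scores, test_months=n_test, test_year=test_year)
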