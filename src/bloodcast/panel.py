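"""Monthly demand panels: validation, CSV I/O, splitting, pandemic imputation.

A :class:`MonthlyPanel` is the universal input of every forecaster in this
package: a contiguous run of calendar years, each carrying one non-negative
demand count per month, with at most a partial *final* year (months 1..k).
Internal gaps are rejected outright — all the classical seasonal methods here
assume dense history, and a silently NaN-padded panel would corrupt monthly
averages.

CSV layouts
-----------
long   columns ``year,month,value``, one row per observation (canonical)
wide   columns ``year,m01..m12``, one row per year (convenience; complete
       years only except a partial last row)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyPanel",
    "PanelError",
    "SplitSpec",
    "read_panel",
    "write_panel",
    "impute_pandemic",
    "split",
]

MONTHS = tuple(range(1, 13))
_WIDE_COLS = ["year"] + [f"m{m:02d}" for m in MONTHS]


class PanelError(ValueError):
    """Raised for malformed, gapped or otherwise invalid panel data."""


@dataclass(frozen=True)
class MonthlyPanel:
    """A year-by-month grid of non-negative demand counts.

    Parameters
    ----------
    label : str
        Series name, e.g. ``"blood_donation"``.
    data : pandas.Series
        Values indexed by a ``(year, month)`` MultiIndex. Validated on
        construction: strictly increasing contiguous years, every non-final
        year complete, partial data only at the tail, all values >= 0.
    """

    label: str
    data: pd.Series = field(compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate(self.data))

    # ---------------------------------------------------------------- alt ctors
    @classmethod
    def from_records(
        cls, label: str, records: Iterable[tuple[int, int, float]]
    ) -> "MonthlyPanel":
        """Build a panel from ``(year, month, value)`` triples."""
        rows = list(records)
        if not rows:
            raise PanelError("empty panel: no observations")
        frame = pd.DataFrame(rows, columns=["year", "month", "value"])
        return cls.from_long_frame(label, frame)

    @classmethod
    def from_long_frame(cls, label: str, frame: pd.DataFrame) -> "MonthlyPanel":
        missing = {"year", "month", "value"} - set(frame.columns)
        if missing:
            raise PanelError(f"long layout missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise PanelError("empty panel: no observations")
        try:
            years = frame["year"].astype(int)
            months = frame["month"].astype(int)
            values = frame["value"].astype(float)
        except (TypeError, ValueError) as exc:
            raise PanelError(f"non-numeric cell in panel: {exc}") from exc
        data = pd.Series(
            values.to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [years.to_numpy(), months.to_numpy()], names=["year", "month"]
            ),
        )
        return cls(label, data)

    @classmethod
    def from_wide_frame(cls, label: str, frame: pd.DataFrame) -> "MonthlyPanel":
        if "year" not in frame.columns:
            raise PanelError("wide layout requires a 'year' column")
        month_cols = [c for c in frame.columns if c != "year"]
        if len(month_cols) != 12:
            raise PanelError(
                f"wide layout requires 12 month columns, found {len(month_cols)}"
            )
        records = []
        for _, row in frame.iterrows():
            year = int(row["year"])
            for m, col in enumerate(month_cols, start=1):
                val = row[col]
                if pd.isna(val):
                    continue  # partial tail year in wide form
                records.append((year, m, float(val)))
        return cls.from_records(label, records)

    # ---------------------------------------------------------------- accessors
    @property
    def years(self) -> list[int]:
        return list(self.data.index.get_level_values("year").unique())

    @property
    def complete_years(self) -> list[int]:
        return [y for y in self.years if len(self.data.loc[y]) == 12]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def value(self, year: int, month: int) -> float:
        return float(self.data.loc[(year, month)])

    def month_values(self, month: int) -> np.ndarray:
        """All available observations of a calendar month, in year order."""
        mask = self.data.index.get_level_values("month") == month
        return self.data[mask].to_numpy()

    def year_values(self, year: int) -> np.ndarray:
        return self.data.loc[year].to_numpy()

    def year_total(self, year: int) -> float:
        return float(self.data.loc[year].sum())

    def to_long_frame(self) -> pd.DataFrame:
        frame = self.data.rename("value").reset_index()
        return frame[["year", "month", "value"]]

    def to_wide_frame(self) -> pd.DataFrame:
        wide = self.data.unstack("month").reindex(columns=list(MONTHS))
        wide.columns = [f"m{m:02d}" for m in MONTHS]
        return wide.reset_index()

    def to_monthly_series(self) -> pd.Series:
        """Values on a monthly PeriodIndex (for ARIMA-style modelling)."""
        idx = pd.PeriodIndex(
            [pd.Period(f"{y}-{m:02d}", freq="M") for y, m in self.data.index],
            name="period",
        )
        return pd.Series(self.data.to_numpy(), index=idx, name=self.label)

    def with_label(self, label: str) -> "MonthlyPanel":
        return MonthlyPanel(label, self.data)

    def equals(self, other: "MonthlyPanel") -> bool:
        return self.data.index.equals(other.data.index) and np.array_equal(
            self.data.to_numpy(), other.data.to_numpy()
        )

    def __len__(self) -> int:
        return self.n_obs

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ys = self.years
        return (
            f"MonthlyPanel(label={self.label!r}, years={ys[0]}..{ys[-1]}, "
            f"n_obs={self.n_obs})"
        )


def _validate(data: pd.Series) -> pd.Series:
    if not isinstance(data.index, pd.MultiIndex) or data.index.nlevels != 2:
        raise PanelError("panel data must be indexed by (year, month)")
    if len(data) == 0:
        raise PanelError("empty panel: no observations")
    data = data.astype(float)
    data.index = data.index.set_names(["year", "month"])

    months = data.index.get_level_values("month")
    bad = months[(months < 1) | (months > 12)]
    if len(bad):
        year = data.index.get_level_values("year")[(months < 1) | (months > 12)][0]
        raise PanelError(f"month out of range 1..12 at (year={year}, month={bad[0]})")

    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise PanelError(f"duplicate observation for (year={dup[0]}, month={dup[1]})")

    neg = data[data < 0]
    if len(neg):
        y, m = neg.index[0]
        raise PanelError(f"negative value at (year={y}, month={m}): {neg.iloc[0]}")

    if not np.isfinite(data.to_numpy()).all():
        raise PanelError("non-finite value in panel")

    data = data.sort_index()
    years = data.index.get_level_values("year").unique().to_list()
    if years != list(range(years[0], years[-1] + 1)):
        raise PanelError(f"years are not contiguous: {years}")

    for i, year in enumerate(years):
        months_present = data.loc[year].index.to_list()
        if i < len(years) - 1:
            if months_present != list(MONTHS):
                missing = sorted(set(MONTHS) - set(months_present))
                raise PanelError(
                    f"internal gap: year {year} missing months {missing}"
                )
        else:  # final year may be a partial head run 1..k
            if months_present != list(range(1, len(months_present) + 1)):
                raise PanelError(
                    f"final year {year} must cover months 1..k, got {months_present}"
                )
    return data


# -------------------------------------------------------------------- file I/O
def read_panel(path: str | Path, layout: str = "long", label: str | None = None) -> MonthlyPanel:
    """Read a panel from CSV.

    ``layout`` is ``"long"`` (columns year,month,value) or ``"wide"``
    (columns year,m01..m12). The label defaults to the file stem.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    frame = pd.read_csv(path, float_precision="round_trip")
    if layout == "long":
        return MonthlyPanel.from_long_frame(label, frame)
    if layout == "wide":
        return MonthlyPanel.from_wide_frame(label, frame)
    raise PanelError(f"unknown layout {layout!r}; expected 'long' or 'wide'")


def write_panel(panel: MonthlyPanel, path: str | Path, layout: str = "long") -> Path:
    """Write a panel to CSV; inverse of :func:`read_panel` cell-for-cell."""
    path = Path(path)
    if layout == "long":
        frame = panel.to_long_frame()
        value_cols = ["value"]
    elif layout == "wide":
        frame = panel.to_wide_frame()
        value_cols = [c for c in frame.columns if c != "year"]
    else:
        raise PanelError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    frame = frame.copy()
    for col in value_cols:
        # shortest-repr serialization makes the round-trip bit-exact
        frame[col] = frame[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    frame.to_csv(path, index=False)
    return path


# ------------------------------------------------------------------ imputation
def impute_pandemic(
    panel: MonthlyPanel,
    impute_years: Sequence[int],
    window: int = 3,
    mode: str = "sequential",
) -> MonthlyPanel:
    """Replace each listed year's months by same-month means of the preceding years.

    This is the rule used to build the pandemic-corrected "data set II"
    variant: each cell ``(y, m)`` with ``y`` in *impute_years* becomes the
    mean of month ``m`` over the ``window`` calendar years immediately before
    ``y``.

    ``mode="sequential"`` lets earlier imputed years feed later ones (2021
    drawing on the already-imputed 2020); ``mode="originals"`` averages only
    pre-imputation values. All other cells are unchanged.
    """
    if mode not in ("sequential", "originals"):
        raise PanelError(f"unknown impute mode {mode!r}")
    if window < 1:
        raise PanelError("window must be >= 1")

    original = panel.data.copy()
    working = panel.data.copy()
    years = set(panel.years)
    for year in sorted(impute_years):
        history = [year - k for k in range(1, window + 1)]
        absent = [y for y in history if y not in years]
        if absent:
            raise PanelError(
                f"cannot impute year {year}: needs {window} preceding years, "
                f"missing {sorted(absent)}"
            )
        source = working if mode == "sequential" else original
        for y in history:
            if len(source.loc[y]) != 12:
                raise PanelError(
                    f"cannot impute year {year}: source year {y} is incomplete"
                )
        if (year, 12) not in working.index:
            raise PanelError(f"cannot impute year {year}: it is incomplete in the panel")
        for m in MONTHS:
            working.loc[(year, m)] = float(
                np.mean([source.loc[(y, m)] for y in history])
            )
    return MonthlyPanel(panel.label, working)


# ----------------------------------------------------------------------- split
@dataclass(frozen=True)
class SplitSpec:
    """Train/test windows as inclusive ``(year, month)`` pairs.

    The default mirrors the canonical protocol of this package: six full
    training years (Jan 2017 – Dec 2022) and a seven-month test window
    (Jan – Jul 2023).
    """

    train_start: tuple[int, int] = (2017, 1)
    train_end: tuple[int, int] = (2022, 12)
    test_start: tuple[int, int] = (2023, 1)
    test_end: tuple[int, int] = (2023, 7)

    def __post_init__(self) -> None:
        for name in ("train_start", "train_end", "test_start", "test_end"):
            y, m = getattr(self, name)
            if not 1 <= m <= 12:
                raise PanelError(f"{name}: month {m} out of range 1..12")
        if not (self.train_start <= self.train_end):
            raise PanelError("train_start must not follow train_end")
        if not (self.test_start <= self.test_end):
            raise PanelError("test_start must not follow test_end")
        if not (self.train_end < self.test_start):
            raise PanelError("train window must precede the test window (no overlap)")
        if self.test_start[0] != self.test_end[0]:
            raise PanelError("test window must lie within one calendar year")
        if self.train_start[1] != 1 or self.test_start[1] != 1:
            raise PanelError(
                "windows must start in January so the sub-panels have no head gap"
            )

    @property
    def test_months(self) -> int:
        return self.test_end[1] - self.test_start[1] + 1

    @property
    def test_year(self) -> int:
        return self.test_start[0]


def _window(panel: MonthlyPanel, start: tuple[int, int], end: tuple[int, int]) -> pd.Series:
    idx = panel.data.index
    keys = list(zip(idx.get_level_values("year"), idx.get_level_values("month")))
    mask = np.array([start <= k <= end for k in keys])
    return panel.data[mask]


def split(panel: MonthlyPanel, spec: SplitSpec | None = None) -> tuple[MonthlyPanel, MonthlyPanel]:
    """Cut a panel into disjoint train and test panels covering exactly *spec*."""
    if spec is None:
        spec = SplitSpec()
    train = _window(panel, spec.train_start, spec.train_end)
    test = _window(panel, spec.test_start, spec.test_end)

    n_train = _n_cells(spec.train_start, spec.train_end)
    n_test = _n_cells(spec.test_start, spec.test_end)
    if len(train) != n_train:
        raise PanelError(
            f"train window {spec.train_start}..{spec.train_end} not fully inside "
            f"panel (expected {n_train} cells, found {len(train)})"
        )
    if len(test) != n_test:
        raise PanelError(
            f"test window {spec.test_start}..{spec.test_end} not fully inside "
            f"panel (expected {n_test} cells, found {len(test)})"
        )
    return MonthlyPanel(panel.label, train), MonthlyPanel(panel.label, test)


def _n_cells(start: tuple[int, int], end: tuple[int, int]) -> int:
    return (end[0] - start[0]) * 12 + end[1] - start[1] + 1
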