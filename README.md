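# bloodcast

Forecasting monthly demand for blood products — whole-blood donations and
issues, random donor platelets (RDP), fresh frozen plasma (FFP) — so that a
blood bank can plan collection and inventory for a perishable product. The
package is aimed at transfusion-service staff and analysts who need a
forecast that is auditable with pencil-and-paper arithmetic, together with
the standard comparators used to judge it.

## Methods

All methods consume a **monthly panel**: a contiguous run of calendar years,
one non-negative count per month, with at most a partial final year.

**SAMAI (simple average with mean annual increment)** — the core method.
With monthly averages `A[m]` across training years, grand average
`G = mean(A)`, seasonal indices `SI[m] = 100·A[m]/G`, annual totals `T[y]`
over complete years, increment ratios `r[y] = T[y]/T[y−1]` and their mean
`R`, the next-year forecast is

```
F[m] = A[m] · R ,   m = 1..12
```

`R > 1` classifies the series as growing. The method assumes stable
multiplicative seasonality and geometric growth, and needs no optimisation.

**Simple average** — `F[m] = A[m]`; SAMAI with the growth scalar removed.

**Ratio-to-trend** — classical decomposition: an ordinary-least-squares line
through the yearly averages (centered at the training midpoint), interpolated
to month midpoints via `t[y][m] = a + b·(y − ȳ) + (b/12)(m − 6.5)`; each cell
is expressed as a percentage of trend, the percentages are averaged by month
and rescaled so the indices mean 100; the forecast is
`F[m] = t[Y][m]·SI[m]/100`, floored at 0.

**Seasonal ARIMA** — ARIMA(p,d,q)(P,D,Q)₁₂ fitted by maximum likelihood
(statsmodels SARIMAX), with an exhaustive minimum-AIC order search, an
augmented Dickey–Fuller stationarity gate, and ACF/PACF diagnostics
(Durbin–Levinson).

**Evaluation** — mean absolute percentage error on a held-out test window,

```
MAPE = (100/n) · Σ |A_t − F_t| / A_t ,
```

assembled into a per-method × per-series × per-variant comparison table with
averaged rows. A **pandemic imputation** rule builds the corrected data
variant ("II"): each designated year's months are replaced by same-month
means of the three preceding years.

## Worked example

```python
from bloodcast import MonthlyPanel, seasonal_profile, increment_summary, samai_forecast

records  = [(2017, m, 100.0 if m != 10 else 220.0) for m in range(1, 13)]
records += [(2018, m, 110.0 if m != 10 else 242.0) for m in range(1, 13)]
panel = MonthlyPanel.from_records("toy", records)

prof = seasonal_profile(panel)
print(prof.grand_avg)            # 115.5
print(prof.seasonal_index[9])    # 200.0        (October spike)

inc = increment_summary(panel)
print(inc.mean_increment)        # 1.1          (totals 1320 -> 1452)

fc = samai_forecast(panel)       # forecast for 2019
print(fc[10], fc[1])             # 254.10000000000002 115.50000000000001
```

October's average (231) is twice the grand average, so its seasonal index is
200; the annual total grew by the factor 1.1, so every monthly average is
scaled up by 1.1 for the next year: October 231 → 254.1, all flat months
105 → 115.5.

The same estimators are available in scikit-learn style
(`SamaiForecaster().fit(panel).predict(2019)`), and a CLI wraps the
workflow:

```
bloodcast simulate --suite --seed 1 --out data/
bloodcast evaluate --config run.yaml --out results/
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch: it generates
the four-series synthetic demand universe (six training years 2017–2022 plus
a Jan–Jul 2023 test window, with a 2020–2021 pandemic dip), builds the
imputed variant, fits all four methods on both variants of every series, and
prints the resulting MAPE comparison table with its averaged rows.

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
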