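# Methods

## Data model

A `MonthlyPanel` holds one demand series as a `(year, month) → value` grid:
years strictly increasing and contiguous, every non-final year complete, an
optional partial final year covering months `1..k`, all values ≥ 0 and
finite. Internal gaps are a validation error, not NaNs — every method here
builds monthly averages or annual totals from dense history, and silently
padded gaps would bias both. Values are stored as reals even though demand
counts are integral, because imputed cells are means. CSV I/O (long layout
`year,month,value`; wide layout `year,m01..m12`) serializes floats with
shortest-repr and reads with round-trip precision, so write-then-read is
bit-exact.

Train/test splitting is window-based (`SplitSpec`); both windows must start
in January so that the sub-panels satisfy the panel invariants, and the test
window must lie inside one calendar year (it is the forecast target year).
The default split is six training years (2017-01..2022-12) and a seven-month
test window (2023-01..2023-07). Seven test months is a configuration
default, not a hard rule; the comparison table records the window it used.

## Pandemic imputation ("variant II")

`impute_pandemic(panel, years, window=3, mode)` replaces each listed year's
month `m` by the mean of month `m` over the `window` immediately preceding
years. Two modes exist because the rule is ambiguous when two consecutive
years are imputed:

- `sequential` (default): years are processed in ascending order and
  previously imputed years feed later ones — the literal reading of
  "previous three years" applied per year (2021 ← mean of 2018, 2019,
  imputed-2020);
- `originals`: only pre-imputation values are averaged.

`originals` re-applied to its own output is idempotent; both modes leave all
non-imputed cells untouched.

## SAMAI

Monthly averages divide by the number of observations actually present for
that month, so a partial tail year contributes to the months it covers;
annual totals and increment ratios use complete years only (totals of a
partial year would not be comparable). The grand average is the mean of the
12 monthly averages; seasonal indices are `100·A[m]/G` and average exactly
100 by construction. The forecast is `F[m] = A[m]·R` for the year after the
last complete training year; forecasting `k` years ahead scales by `R^k`,
an extension the estimator flags by accepting any later target year (the
method itself defines only next-year prediction). Two algebraic identities
are exploited in tests: `Σ F = R · mean(T)`, and SAMAI equals the
simple-average forecast scaled by the single scalar `R`.

No non-negativity clipping is needed: non-negative inputs make every
quantity non-negative.

## Ratio-to-trend

The annual trend is OLS of the yearly averages `T[y]/12` on the year index
centered at the arithmetic midpoint of the training years; with a centered
regressor the intercept is simply the mean yearly average. "Season" is
calendar month throughout; the month-level trend places month `m` at its
own midpoint, `(m − 6.5)/12` of a year from the annual midpoint, which
reproduces exactly any series linear in serial month index. Per-cell ratios
`100·X/t` require strictly positive trend values over the training cells
(otherwise an error naming the first offending cell); the correction factor
is `1200 / Σ(month-average ratios)`, equivalently division by their grand
average, which forces `mean(SI) = 100`. Forecasts are floored at 0 when a
falling trend extrapolates below zero, since demand counts cannot be
negative.

A known bias, demonstrated in the tests rather than hidden: when the true
level is constant within each year and jumps between years (a staircase),
the within-year trend interpolation tilts the recovered indices by roughly
`±(b/2)/level` relative at the year's edges — about 3 index points at 10%
annual growth. The recipe is exact when the underlying trend itself moves
linearly month to month.

## Seasonal ARIMA

Coefficient estimation, the ADF regression machinery and likelihood
evaluation are delegated to statsmodels (`SARIMAX`, `adfuller`); this
package owns the order search, the decomposition, the ACF/PACF diagnostics
and the reporting contract.

- **Search.** Exhaustive grid within bounds (defaults `p,q ≤ 3`, `d ≤ 2`,
  `P,Q ≤ 2`, `D ≤ 1`, `s = 12`), each candidate fitted by maximum
  likelihood; the converged candidate with minimum AIC wins, ties broken by
  fewer estimated parameters, then lexicographically on `(p,d,q,P,D,Q)`.
  Exhaustive search was chosen over stepwise for reproducibility; a
  `stepwise=True` hill-climb from standard seeds is offered for speed. An
  intercept is included only for undifferenced models (`trend="auto"`), the
  convention of the usual auto-ARIMA tools. Failed or non-converged
  candidates are recorded and excluded; if nothing converges the error
  lists every attempt. The default grid is large (~2.6k candidates); for
  interactive use and for the bundled scripts, narrower explicit bounds
  (e.g. all orders ≤ 1) are passed through the constructor.
- **ADF gate.** Lag order selected by AIC (the common default; the choice
  is not otherwise constrained). Rejection at α = 0.05 reports the series
  stationary. Constant or too-short (< 24 obs) series are errors.
- **Decomposition.** Centered 2×12 moving average trend (half weight at the
  ends), month-wise means of detrended values normalized to sum 0
  (additive) or mean 1 (multiplicative), residual as remainder; matches the
  textbook procedure and is cross-checked against statsmodels'
  `seasonal_decompose` in the tests.
- **ACF/PACF.** Sample ACF with the biased (1/n) convention; PACF by the
  Durbin–Levinson recursion on that ACF, i.e. the Yule–Walker solution —
  verified in tests against a direct Toeplitz solve of the same equations.
  (The OLS-on-lags PACF estimator differs from Yule–Walker at O(1/n); the
  two must not be conflated in exactness checks.)
- **Forecasts** are point predictions floored at 0 for reporting.

## Evaluation

`mape` implements `(100/n)·Σ|A_t − F_t|/A_t`; zero actuals raise an error
naming the offending index rather than being skipped — the formula divides
by `A_t` and demand counts in this domain are positive. MAPE is
scale-invariant, which the property tests exercise.

`compare_methods` fits every method on every `(series, variant)` training
panel, forecasts the shared test window, and assembles the comparison
table. Averaged rows are arithmetic means of the constituent per-series
MAPEs; the combined row averages all per-series values (not the variant
averages — these coincide only when variant counts match). Failed cells are
recorded with their error, excluded from averages, and flagged in the text
rendering. Internal values keep full precision; rounding to two decimals
happens only at presentation.

## Synthetic worlds

The generator states: `X[y][m] = L · R^(y−1) · SI[m]/100 · shock(y) ·
(1 + ε)` with `ε ~ N(0, cv)` truncated so values stay non-negative, a flat
multiplier `shock(y)` in designated shock years, and an optional partial
extra year for the test window. Multiplicative *Gaussian* noise (not
lognormal) was chosen for transparency: oracles can reproduce it exactly,
and at cv = 5% truncation is a ~10⁻⁸⁹ tail event. Fixed seed implies
bit-identical panels.

The four-series demo universe (`paper_like_suite`) emulates a regional
blood-bank's registers: seasonal profiles with spring/autumn donation
peaks, a dengue-season (Sep–Nov) platelet surge and a December plasma peak;
year-over-year growth ratios 1.092 (donation), 1.029 (issue), 1.388 (RDP),
1.111 (FFP); base levels 560/630/80/100 units·month⁻¹ chosen so six-year
mean levels land in the plausible range for such a centre; noise cv 0.05; a
flat 30% pandemic dip (`shock_factor = 0.7`) in 2020–2021 — the dip's depth
is not pinned down by anything stronger than "notable decline", so 0.7 was
chosen once as a realistic middle value and not revisited. Variant II of
the suite applies the pandemic imputation to the shock years.

What a green recovery test establishes: the estimators' arithmetic on a
world that satisfies their assumptions exactly. What it does not: calendar
effects (festival or campaign spikes), month-shaped shocks, serially
correlated demand, or any guarantee about a particular hospital's data.

Seeds in stochastic demonstrations are fixed a priori (seed 0, or small
named constants) and are part of the stated world: e.g. the ±3-index-point
seasonal-index recovery band at cv = 5% with a 200-point October peak is
about 1.5 sampling standard deviations for the peak month, so it is a
typical-case demonstration at a fixed seed, not a uniform guarantee.

## Known limitations

- SAMAI provides no prediction intervals; SARIMA intervals beyond the
  delegated estimator's are out of scope.
- MAPE is the only score (no sMAPE/MASE/RMSE); the comparison table is the
  documented extension point.
- No quarterly-season variant of ratio-to-trend, no
  ratio-to-moving-average method, no exponential-smoothing comparator.
- Monthly resolution only: no day-level structure, no calendar-effect
  covariates, no database connectivity.
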