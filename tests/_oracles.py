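"""Independent brute-force reference implementations used only by tests.

These follow the arithmetic recipes literally, in plain Python, without
sharing any code with the package under test.
"""

from __future__ import annotations


def samai_bruteforce(cells: dict[tuple[int, int], float]):
    """Literal step-by-step simple-average-with-mean-annual-increment.

    ``cells`` maps (year, month) -> value. Returns (A, G, SI, R, F) with A,
    SI, F as 12-lists indexed by month-1.
    """
    # step 1: arrange year-wise on monthly basis
    years = sorted({y for y, _ in cells})
    # step 2: monthly averages over however many observations each month has
    A = []
    for m in range(1, 13):
        obs = [cells[(y, m)] for y in years if (y, m) in cells]
        A.append(sum(obs) / len(obs))
    # step 3: grand average
    G = sum(A) / 12
    # step 4: seasonal index
    SI = [100 * a / G for a in A]
    # step 5: annual totals (complete years only)
    complete = [y for y in years if all((y, m) in cells for m in range(1, 13))]
    T = [sum(cells[(y, m)] for m in range(1, 13)) for y in complete]
    # steps 6-8: increment ratios and their mean
    ratios = [T[i] / T[i - 1] for i in range(1, len(T))]
    R = sum(ratios) / len(ratios)
    # step 9: next-year prediction
    F = [a * R for a in A]
    return A, G, SI, R, F


def trend_bruteforce(year_averages: dict[int, float]):
    """Normal-equations least squares of yearly averages on centered year.

    Returns (intercept, slope, origin) with origin the arithmetic midpoint.
    """
    years = sorted(year_averages)
    n = len(years)
    origin = sum(years) / n
    xs = [y - origin for y in years]
    ys = [year_averages[y] for y in years]
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = sum(ys) / n  # centered regressor: intercept is the mean
    return intercept, slope, origin


def yule_walker_pacf(rho):
    """PACF by direct solve of the Yule–Walker Toeplitz systems.

    ``rho`` is the sample ACF (rho[0] = 1). Returns pacf[0..nlags] with
    pacf[k] the last coefficient of the order-k system solution.
    """
    import numpy as np

    nlags = len(rho) - 1
    out = [1.0]
    for k in range(1, nlags + 1):
        Rk = np.array([[rho[abs(i - j)] for j in range(k)] for i in range(k)])
        rk = np.array(rho[1 : k + 1])
        out.append(float(np.linalg.solve(Rk, rk)[-1]))
    return out
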