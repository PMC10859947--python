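import numpy as np
import pytest

from bloodcast import MonthlyPanel


def make_panel(label, year_values):
    """Panel from {year: 12-list or scalar} (scalar = constant year)."""
    records = []
    for year, vals in year_values.items():
        if np.isscalar(vals):
            vals = [vals] * 12
        records.extend((year, m, float(v)) for m, v in enumerate(vals, start=1))
    return MonthlyPanel.from_records(label, records)


def random_panel(rng, n_years=None, lo=1.0, hi=1000.0, label="random"):
    """Complete-years panel with iid uniform values (oracle-test input)."""
    if n_years is None:
        n_years = int(rng.integers(2, 7))
    start = int(rng.integers(2000, 2020))
    return make_panel(
        label, {start + i: rng.uniform(lo, hi, 12).tolist() for i in range(n_years)}
    )


@pytest.fixture
def two_year_panel():
    """Two years, flat except an October spike: the worked SAMAI example.

    Monthly averages 105 (Oct 231), grand average 115.5, SI[Oct] = 200,
    annual totals 1320 and 1452, R = 1.1.
    """
    y1 = [100.0] * 12
    y1[9] = 220.0
    y2 = [110.0] * 12
    y2[9] = 242.0
    return make_panel("toy", {2017: y1, 2018: y2})


@pytest.fixture
def constant_panel():
    return make_panel("const", {2017: 50.0, 2018: 50.0, 2019: 50.0})


@pytest.fixture
def three_year_ramp():
    """Jan values 90/100/110 with matching flat years (imputation example)."""
    return make_panel("ramp", {2017: 90.0, 2018: 100.0, 2019: 110.0})


def linear_panel(n_years=4, alpha=200.0, beta=1.5, start=2017, label="line"):
    """X[y][m] = alpha + beta * u with u the serial month index 1..12n."""
    vals = {}
    u = 1
    for i in range(n_years):
        row = []
        for _ in range(12):
            row.append(alpha + beta * u)
            u += 1
        vals[start + i] = row
    return make_panel(label, vals)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
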