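import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bloodcast import (
    MonthlyPanel,
    PanelError,
    SplitSpec,
    impute_pandemic,
    read_panel,
    split,
    write_panel,
)

from conftest import make_panel


# ------------------------------------------------------------------ validation
@pytest.mark.parametrize(
    "records, match",
    [
        ([(2017, 13, 5.0)], "month"),
        ([(2017, 0, 5.0)], "month"),
        ([(2017, 1, 5.0), (2017, 1, 6.0)], "duplicate"),
        ([(2017, 1, -5.0)], "negative"),
        ([], "empty"),
    ],
)
def test_invalid_records_rejected(records, match):
    with pytest.raises(PanelError, match=match):
        MonthlyPanel.from_records("bad", records)


def test_internal_gap_rejected():
    records = [(2017, m, 1.0) for m in range(1, 13) if m != 5]
    records += [(2018, m, 1.0) for m in range(1, 13)]
    with pytest.raises(PanelError, match="gap"):
        MonthlyPanel.from_records("bad", records)


def test_non_contiguous_years_rejected():
    records = [(2017, m, 1.0) for m in range(1, 13)]
    records += [(2019, m, 1.0) for m in range(1, 13)]
    with pytest.raises(PanelError, match="contiguous"):
        MonthlyPanel.from_records("bad", records)


def test_partial_year_allowed_only_at_tail():
    ok = [(2017, m, 1.0) for m in range(1, 13)] + [(2018, m, 2.0) for m in (1, 2, 3)]
    panel = MonthlyPanel.from_records("tail", ok)
    assert panel.complete_years == [2017]
    assert panel.n_obs == 15
    # a tail year must cover a head run 1..k, not arbitrary months
    bad = [(2017, m, 1.0) for m in range(1, 13)] + [(2018, 5, 2.0)]
    with pytest.raises(PanelError, match="1..k"):
        MonthlyPanel.from_records("bad", bad)


# ------------------------------------------------------------------------- I/O
@pytest.mark.parametrize("layout", ["long", "wide"])
def test_roundtrip_exact(tmp_path, layout):
    rng = np.random.default_rng(7)
    vals = {2017 + i: rng.uniform(0, 900, 12).tolist() for i in range(3)}
    panel = make_panel("rt", vals)
    path = tmp_path / "p.csv"
    write_panel(panel, path, layout=layout)
    back = read_panel(path, layout=layout, label="rt")
    assert back.equals(panel)


def test_roundtrip_partial_tail_long(tmp_path):
    records = [(2017, m, float(m)) for m in range(1, 13)]
    records += [(2018, m, float(10 * m)) for m in (1, 2)]
    panel = MonthlyPanel.from_records("pt", records)
    path = tmp_path / "p.csv"
    write_panel(panel, path, layout="long")
    frame = pd.read_csv(path)
    assert len(frame) == 14  # only present months written
    assert read_panel(path, label="pt").equals(panel)


def test_layout_equivalence(tmp_path):
    panel = make_panel("eq", {2017: list(range(550, 562))})
    pl = tmp_path / "long.csv"
    pw = tmp_path / "wide.csv"
    write_panel(panel, pl, layout="long")
    write_panel(panel, pw, layout="wide")
    assert read_panel(pl, layout="long", label="eq").equals(
        read_panel(pw, layout="wide", label="eq")
    )


def test_read_errors_name_offender(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("year,month,value\n2017,13,5\n")
    with pytest.raises(PanelError, match="month.*13"):
        read_panel(path)


@settings(max_examples=25, derandomize=True)
@given(
    n_years=st.integers(1, 4),
    tail=st.integers(0, 11),
    seed=st.integers(0, 2**16),
    layout=st.sampled_from(["long", "wide"]),
)
def test_roundtrip_property(tmp_path_factory, n_years, tail, seed, layout):
    """Write-then-read reproduces every cell exactly, both layouts."""
    rng = np.random.default_rng(seed)
    records = [
        (2000 + i, m, float(rng.uniform(0, 1e4)))
        for i in range(n_years)
        for m in range(1, 13)
    ]
    records += [(2000 + n_years, m, float(rng.uniform(0, 1e4))) for m in range(1, tail + 1)]
    panel = MonthlyPanel.from_records("prop", records)
    path = tmp_path_factory.mktemp("rt") / "p.csv"
    write_panel(panel, path, layout=layout)
    assert read_panel(path, layout=layout, label="prop").equals(panel)


# -------------------------------------------------------------------- imputation
def test_impute_mean_of_three():
    panel = make_panel(
        "t", {2017: 90.0, 2018: 100.0, 2019: 110.0, 2020: 5.0}
    )
    out = impute_pandemic(panel, [2020])
    assert out.value(2020, 1) == pytest.approx(100.0)
    # all non-imputed cells untouched
    for y in (2017, 2018, 2019):
        assert np.array_equal(out.year_values(y), panel.year_values(y))


def test_impute_sequential_two_step():
    panel = make_panel(
        "t", {2017: 90.0, 2018: 100.0, 2019: 110.0, 2020: 1.0, 2021: 1.0}
    )
    out = impute_pandemic(panel, [2020, 2021], mode="sequential")
    assert out.value(2020, 1) == pytest.approx(100.0)
    assert out.value(2021, 1) == pytest.approx((100.0 + 110.0 + 100.0) / 3)


def test_impute_originals_mode():
    panel = make_panel(
        "t", {2017: 90.0, 2018: 100.0, 2019: 110.0, 2020: 10.0, 2021: 10.0}
    )
    out = impute_pandemic(panel, [2020, 2021], mode="originals")
    # 2021 averages the original (shocked) 2020, not the imputed one
    assert out.value(2021, 1) == pytest.approx((100.0 + 110.0 + 10.0) / 3)


def test_impute_constant_idempotent(constant_panel):
    panel = make_panel("c", {y: 50.0 for y in range(2017, 2022)})
    out = impute_pandemic(panel, [2020])
    assert out.equals(panel)
    # originals mode re-applied gives the same result again
    assert impute_pandemic(out, [2020], mode="originals").equals(out)


def test_impute_insufficient_history():
    panel = make_panel("t", {2017: 1.0, 2018: 1.0})
    with pytest.raises(PanelError, match="2018"):
        impute_pandemic(panel, [2018], window=3)


# ------------------------------------------------------------------------ split
def test_split_canonical_window():
    vals = {y: float(y) for y in range(2017, 2023)}
    vals[2023] = [float(m) for m in range(1, 13)]
    panel = make_panel("s", vals)
    train, test = split(panel, SplitSpec())
    assert train.n_obs == 72
    assert test.n_obs == 7
    assert train.years == list(range(2017, 2023))
    assert test.years == [2023]
    # disjoint and inside the panel
    assert set(train.data.index).isdisjoint(test.data.index)
    excluded = panel.n_obs - train.n_obs - test.n_obs
    assert excluded == 5  # Aug-Dec 2023


def test_split_window_outside_panel():
    panel = make_panel("s", {2017: 1.0, 2018: 1.0})
    with pytest.raises(PanelError, match="test window"):
        split(panel, SplitSpec(train_start=(2017, 1), train_end=(2018, 12),
                               test_start=(2019, 1), test_end=(2019, 7)))


def test_split_overlap_rejected():
    with pytest.raises(PanelError, match="precede"):
        SplitSpec(train_start=(2017, 1), train_end=(2022, 12),
                  test_start=(2022, 1), test_end=(2022, 7))


def test_split_test_window_single_year():
    with pytest.raises(PanelError, match="one calendar year"):
        SplitSpec(train_start=(2017, 1), train_end=(2021, 12),
                  test_start=(2022, 1), test_end=(2023, 1))
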