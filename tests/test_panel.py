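import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelcausal import BalancedPanel, first_difference, read_long_panel, write_long_panel
from panelcausal.panel import DuplicateCellError, PanelError, ParseError, UnbalancedPanelError


def test_round_trip_is_lossless(small_panel, tmp_path):
    path = tmp_path / "panel.csv"
    write_long_panel(small_panel, path)
    back = read_long_panel(path)
    assert back.unit_ids == small_panel.unit_ids
    assert back.periods == small_panel.periods
    for v in small_panel.variables:
        np.testing.assert_array_equal(back.matrix(v), small_panel.matrix(v))


def test_row_order_does_not_matter(small_panel, tmp_path):
    path = tmp_path / "sorted.csv"
    write_long_panel(small_panel, path)
    header, *rows = path.read_text().strip().split("\n")
    rng = np.random.default_rng(3)
    path2 = tmp_path / "shuffled.csv"
    path2.write_text("\n".join([header] + [rows[i] for i in rng.permutation(len(rows))]))
    a, b = read_long_panel(path), read_long_panel(path2)
    for v in a.variables:
        np.testing.assert_array_equal(a.matrix(v), b.matrix(v))


def test_missing_cell_is_named(small_panel, tmp_path):
    path = tmp_path / "gap.csv"
    df = small_panel.to_long()
    df = df[~((df.country == "B") & (df.year == 2002))]
    df.to_csv(path, index=False)
    with pytest.raises(UnbalancedPanelError, match="'B'.*2002"):
        read_long_panel(path)


def test_duplicate_row_rejected(small_panel, tmp_path):
    path = tmp_path / "dup.csv"
    df = small_panel.to_long()
    pd.concat([df, df.iloc[[0]]]).to_csv(path, index=False)
    with pytest.raises(DuplicateCellError):
        read_long_panel(path)


def test_non_numeric_cell_located(small_panel, tmp_path):
    path = tmp_path / "bad.csv"
    df = small_panel.to_long().astype({"hexp": object})
    df.loc[3, "hexp"] = "oops"
    df.to_csv(path, index=False)
    with pytest.raises(ParseError, match="hexp"):
        read_long_panel(path)


@pytest.mark.parametrize(
    "series,expected",
    [
        ([1.0, 3.0, 6.0, 6.5, 7.0, 8.0], [2.0, 3.0, 0.5, 0.5, 1.0]),
        ([4.0] * 6, [0.0] * 5),
    ],
)
def test_first_difference_arithmetic(series, expected):
    panel = BalancedPanel(
        ["A", "B"],
        list(range(2000, 2006)),
        {"y": np.array([series, series])},
    )
    diffed = first_difference(panel, "y")
    assert diffed.T == panel.T - 1
    np.testing.assert_allclose(diffed.matrix("y")[0], expected)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_difference_then_cumsum_restores_series(seed):
    """Differencing is inverted exactly by cumulative summation from the
    stored initial value (random-walk draws)."""
    r = np.random.default_rng(seed)
    y = np.cumsum(r.normal(size=(3, 12)), axis=1)
    panel = BalancedPanel(["a", "b", "c"], list(range(12)), {"y": y})
    d = first_difference(panel, "y").matrix("y")
    restored = y[:, [0]] + np.cumsum(d, axis=1)
    np.testing.assert_allclose(restored, y[:, 1:], rtol=1e-12, atol=1e-12)


def test_panel_invariants_enforced():
    with pytest.raises(PanelError):
        BalancedPanel(["A"], list(range(2000, 2005)), {})  # N < 2
    with pytest.raises(PanelError):
        BalancedPanel(["A", "B"], [2000, 2002, 2003, 2004, 2005], {})  # gap
    with pytest.raises(PanelError):
        BalancedPanel(
            ["A", "B"], list(range(2000, 2005)), {"y": np.full((2, 5), np.nan)}
        )


def test_negative_values_allowed(small_panel):
    # net-migration-like series can be negative
    assert (small_panel.matrix("migr") < 0).any()
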