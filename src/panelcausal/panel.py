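"""Balanced country-year panel container and long-format I/O.

All downstream stages (dependence diagnostics, unit-root tests, causality
tests, CS-ARDL) consume :class:`BalancedPanel`, which stores one dense
``N x T`` float matrix per variable plus explicit unit/period index maps.
The file representation (long CSV/TSV) never leaks past this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BalancedPanel",
    "VariableSpec",
    "PanelError",
    "UnbalancedPanelError",
    "DuplicateCellError",
    "ParseError",
    "read_long_panel",
    "write_long_panel",
    "first_difference",
]


class PanelError(ValueError):
    """Base class for panel construction/validation failures."""


class UnbalancedPanelError(PanelError):
    """A (unit, period, variable) cell is missing."""


class DuplicateCellError(PanelError):
    """A (unit, period) row appears more than once."""


class ParseError(PanelError):
    """A cell could not be read as a finite number."""


@dataclass(frozen=True)
class VariableSpec:
    """Descriptive metadata for one panel variable.

    ``indicator_code`` holds the upstream database code (e.g. a World Bank
    WDI indicator) when the series has one; it is never used in computation.
    """

    name: str
    units: str = ""
    indicator_code: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be nonempty")


@dataclass
class BalancedPanel:
    """A balanced panel: ``N`` units observed at the same ``T`` periods.

    Parameters
    ----------
    unit_ids
        Ordered unit labels (countries), length ``N``.
    periods
        Ordered integer time labels (years), strictly increasing and
        consecutive; only their order is ever used in estimation.
    data
        Mapping variable name -> float array of shape ``(N, T)``.
    """

    unit_ids: list[str]
    periods: list[int]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.periods = [int(p) for p in self.periods]
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise PanelError("duplicate unit ids")
        if self.N < 2:
            raise PanelError(f"need at least 2 units, got {self.N}")
        if self.T < 5:
            raise PanelError(f"need at least 5 periods, got {self.T}")
        diffs = np.diff(self.periods)
        if not np.all(diffs == 1):
            raise PanelError("periods must be strictly increasing consecutive integers")
        clean: dict[str, np.ndarray] = {}
        for name, mat in self.data.items():
            arr = np.asarray(mat, dtype=float)
            if arr.shape != (self.N, self.T):
                raise PanelError(
                    f"variable {name!r}: shape {arr.shape} != (N={self.N}, T={self.T})"
                )
            if not np.all(np.isfinite(arr)):
                i, t = np.argwhere(~np.isfinite(arr))[0]
                raise UnbalancedPanelError(
                    f"non-finite value for variable {name!r}, unit "
                    f"{self.unit_ids[i]!r}, period {self.periods[t]}"
                )
            clean[name] = arr
        self.data = clean

    # -- basic accessors ---------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.unit_ids)

    @property
    def T(self) -> int:
        return len(self.periods)

    @property
    def variables(self) -> list[str]:
        return list(self.data)

    def matrix(self, variable: str) -> np.ndarray:
        """Return the ``(N, T)`` value matrix for ``variable`` (a view)."""
        try:
            return self.data[variable]
        except KeyError:
            raise KeyError(f"unknown variable {variable!r}; have {self.variables}") from None

    def series(self, variable: str, unit: str) -> np.ndarray:
        """One unit's series for ``variable``, length ``T``."""
        return self.matrix(variable)[self.unit_ids.index(unit)]

    def subset(self, variables: list[str]) -> "BalancedPanel":
        return BalancedPanel(
            self.unit_ids, self.periods, {v: self.matrix(v).copy() for v in variables}
        )

    def to_long(
        self, unit_col: str = "country", period_col: str = "year"
    ) -> pd.DataFrame:
        """Long-format frame, one row per (unit, period), one column per variable."""
        idx = pd.MultiIndex.from_product(
            [self.unit_ids, self.periods], names=[unit_col, period_col]
        )
        cols = {v: self.data[v].ravel() for v in self.variables}
        return pd.DataFrame(cols, index=idx).reset_index()


def read_long_panel(
    path,
    unit_col: str = "country",
    period_col: str = "year",
    var_cols: list[str] | None = None,
    sep: str | None = None,
) -> BalancedPanel:
    """Read a long-format delimited text file into a validated panel.

    The file must have a header row and one row per (unit, period). Row
    order is irrelevant. Missing cells, duplicated rows and non-numeric
    values are hard errors naming the offending location.
    """
    if sep is None:
        # sniff the delimiter from the header, then use the C engine with
        # round-trip float parsing so writes and reads are lossless
        with open(path) as f:
            header = f.readline()
        sep = "\t" if "\t" in header else ";" if ";" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (unit_col, period_col):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in {path}")
    if var_cols is None:
        var_cols = [c for c in df.columns if c not in (unit_col, period_col)]
    if not var_cols:
        raise ParseError("no variable columns found")

    dup = df.duplicated(subset=[unit_col, period_col])
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicateCellError(
            f"duplicate row for unit {row[unit_col]!r}, period {row[period_col]!r}"
        )

    units = sorted(df[unit_col].astype(str).unique())
    try:
        periods = sorted(int(p) for p in df[period_col].unique())
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-integer period label: {exc}") from None

    n, t = len(units), len(periods)
    if len(df) != n * t:
        # locate one concrete gap for the error message
        have = set(zip(df[unit_col].astype(str), df[period_col].astype(int)))
        for u in units:
            for p in periods:
                if (u, p) not in have:
                    raise UnbalancedPanelError(
                        f"unbalanced panel: missing row for unit {u!r}, period {p}"
                    )
        raise UnbalancedPanelError("unbalanced panel")

    uix = {u: i for i, u in enumerate(units)}
    pix = {p: j for j, p in enumerate(periods)}
    rows = df[unit_col].astype(str).map(uix).to_numpy()
    cols = df[period_col].astype(int).map(pix).to_numpy()

    data: dict[str, np.ndarray] = {}
    for v in var_cols:
        vals = pd.to_numeric(df[v], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            k = int(np.argmax(bad))
            raise ParseError(
                f"non-numeric value {df[v].iloc[k]!r} for variable {v!r}, unit "
                f"{df[unit_col].iloc[k]!r}, period {df[period_col].iloc[k]!r}"
            )
        mat = np.empty((n, t))
        mat[rows, cols] = vals
        data[v] = mat
    return BalancedPanel(units, periods, data)


def write_long_panel(
    panel: BalancedPanel,
    path,
    unit_col: str = "country",
    period_col: str = "year",
    sep: str = ",",
) -> None:
    """Write the panel in the same long format `read_long_panel` accepts."""
    panel.to_long(unit_col, period_col).to_csv(path, sep=sep, index=False)


def first_difference(panel: BalancedPanel, variable: str) -> BalancedPanel:
    """First-difference one variable: returns a single-variable panel with
    ``T - 1`` periods where ``dy[i, t] = y[i, t] - y[i, t-1]``.

    The returned panel keeps the variable's name; its periods are the
    original periods with the first dropped (a difference dated at period
    ``t`` uses the level change into ``t``).
    """
    y = panel.matrix(variable)
    if panel.T < 6:
        raise PanelError("need T >= 6 so the differenced panel keeps T >= 5")
    return BalancedPanel(
        panel.unit_ids, panel.periods[1:], {variable: np.diff(y, axis=1)}
    )
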