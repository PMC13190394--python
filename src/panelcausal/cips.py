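"""Second-generation panel unit-root testing (CADF / CIPS).

Each unit's ADF regression is augmented with the cross-sectional averages
of the lagged level and of the first differences, which absorb a single
common factor and make the test robust to cross-sectional dependence. The
panel statistic (CIPS) is the arithmetic mean of the unit CADF t-ratios.

Critical values are non-standard; the embedded tables in ``_cips_cv`` were
obtained by direct Monte Carlo simulation of independent random walks with
the cross-average augmentation included (100 000 replications per (N, T)
grid point), the same experiment that defines the published tables. A
seeded :func:`simulate_cips_critical_values` reproduces any entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cips_cv import CV_TABLES, N_GRID, T_GRID
from .panel import BalancedPanel, first_difference

__all__ = [
    "CADFResult",
    "CIPSResult",
    "IntegrationSummary",
    "cadf",
    "cips",
    "integration_order",
    "cips_critical_values",
    "simulate_cips_critical_values",
]

# published-style truncation bounds for individual CADF t-ratios
_TRUNC = {"constant": (-6.19, 2.61), "constant_trend": (-6.42, 1.70)}


@dataclass(frozen=True)
class CADFResult:
    unit_id: str
    t_statistic: float
    lag_order: int
    deterministic: str  # "constant" | "constant_trend"


@dataclass(frozen=True)
class CIPSResult:
    cips: float
    per_unit: list[CADFResult]
    decision: dict[float, str]  # level -> "reject" | "fail_to_reject"
    critical_values: dict[float, float]  # level -> CV
    N: int
    T: int

    def rejects(self, level: float = 0.05) -> bool:
        return self.decision[level] == "reject"


@dataclass(frozen=True)
class IntegrationSummary:
    orders: dict[str, int]  # variable -> 0 or 1
    dmax: int


def _design(
    y: np.ndarray,
    ybar: np.ndarray,
    p: int,
    deterministic: str,
    dybar: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Build the CADF regression (response dy_t, regressor matrix) for one
    unit. Column 1 (0-based, after deterministics) is the lagged level whose
    t-ratio is the CADF statistic."""
    T = y.size
    dy = np.diff(y)
    if dybar is None:
        dybar = np.diff(ybar)
    t0 = p + 1  # first usable index into dy (0-based)
    rows = T - 1 - t0
    det_cols = 1 + (deterministic == "constant_trend")
    ncol = det_cols + 3 + 2 * p
    if rows <= ncol:
        raise ValueError(f"insufficient observations: {rows} rows, {ncol} regressors")
    X = np.empty((rows, ncol))
    X[:, 0] = 1.0
    c = 1
    if deterministic == "constant_trend":
        X[:, 1] = np.arange(rows, dtype=float)
        c = 2
    X[:, c] = y[t0:-1]  # y_{t-1}
    X[:, c + 1] = ybar[t0:-1]  # ybar_{t-1}
    X[:, c + 2] = dybar[t0:]  # d ybar_t
    for j in range(1, p + 1):
        X[:, c + 2 + j] = dy[t0 - j : -j]
        X[:, c + 2 + p + j] = dybar[t0 - j : -j]
    return dy[t0:], X, c


def cadf(
    series: np.ndarray,
    cross_avg_level: np.ndarray,
    cross_avg_diff: np.ndarray | None = None,
    p: int = 1,
    deterministic: str = "constant",
    unit_id: str = "",
) -> CADFResult:
    """Cross-sectionally augmented Dickey–Fuller t-ratio for one unit.

    ``cross_avg_diff`` (length ``T - 1``) may be omitted; it is then derived
    from the level averages.
    """
    if deterministic not in _TRUNC:
        raise ValueError("deterministic must be 'constant' or 'constant_trend'")
    y = np.asarray(series, dtype=float)
    ybar = np.asarray(cross_avg_level, dtype=float)
    if y.shape != ybar.shape:
        raise ValueError("series and cross-average must share length")
    dybar = None
    if cross_avg_diff is not None:
        dybar = np.asarray(cross_avg_diff, dtype=float)
        if dybar.size != y.size - 1:
            raise ValueError("cross_avg_diff must have length T - 1")
    dyt, X, lag_col = _design(y, ybar, p, deterministic, dybar)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear CADF regressors for unit {unit_id!r} "
            "(is the unit identical to the cross-sectional average?)"
        )
    beta, res, *_ = np.linalg.lstsq(X, dyt, rcond=None)
    resid = dyt - X @ beta
    dof = X.shape[0] - X.shape[1]
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[lag_col, lag_col])
    t = float(beta[lag_col] / se)
    lo, hi = _TRUNC[deterministic]
    t = min(max(t, lo), hi)
    return CADFResult(unit_id, t, p, deterministic)


def cips_critical_values(
    N: int, T: int, deterministic: str = "constant"
) -> dict[float, float]:
    """Critical values for CIPS at the 1/5/10% levels, bilinear in (N, T)
    over the embedded simulated grid (clamped at the grid edges)."""
    tab = CV_TABLES[deterministic]

    def _bracket(grid: tuple[int, ...], v: int) -> tuple[int, int, float]:
        g = list(grid)
        if v <= g[0]:
            return 0, 0, 0.0
        if v >= g[-1]:
            return len(g) - 1, len(g) - 1, 0.0
        hi = next(i for i, gv in enumerate(g) if gv >= v)
        if g[hi] == v:
            return hi, hi, 0.0
        lo = hi - 1
        return lo, hi, (v - g[lo]) / (g[hi] - g[lo])

    i0, i1, wn = _bracket(N_GRID, N)
    j0, j1, wt = _bracket(T_GRID, T)
    out = {}
    for lvl in (0.01, 0.05, 0.10):
        q = tab[lvl]
        v = (
            (1 - wn) * (1 - wt) * q[i0][j0]
            + (1 - wn) * wt * q[i0][j1]
            + wn * (1 - wt) * q[i1][j0]
            + wn * wt * q[i1][j1]
        )
        out[lvl] = float(v)
    return out


def cips(
    panel: BalancedPanel,
    variable: str,
    p: int = 1,
    deterministic: str = "constant",
) -> CIPSResult:
    """CIPS statistic for one variable: mean of unit CADF t-ratios, with
    reject/fail decisions against the embedded critical values."""
    if panel.N < 2:
        raise ValueError("cross-sectional averages need N >= 2")
    y = panel.matrix(variable)
    ybar = y.mean(axis=0)
    per_unit = [
        cadf(y[i], ybar, None, p, deterministic, unit_id=panel.unit_ids[i])
        for i in range(panel.N)
    ]
    stat = float(np.mean([r.t_statistic for r in per_unit]))
    cvs = cips_critical_values(panel.N, panel.T, deterministic)
    decision = {
        lvl: ("reject" if stat < cv else "fail_to_reject") for lvl, cv in cvs.items()
    }
    return CIPSResult(stat, per_unit, decision, cvs, panel.N, panel.T)


def integration_order(
    panel: BalancedPanel,
    variables: list[str] | None = None,
    max_diff: int = 1,
    p: int = 1,
    deterministic: str = "constant",
    level: float = 0.05,
) -> IntegrationSummary:
    """Classify each variable I(0)/I(1) by CIPS on levels then differences;
    ``dmax`` is the maximum order across variables."""
    orders: dict[str, int] = {}
    for v in variables or panel.variables:
        cur = panel
        for d in range(max_diff + 1):
            if cips(cur, v, p, deterministic).rejects(level):
                orders[v] = d
                break
            if d < max_diff:
                cur = first_difference(cur, v)
        else:
            raise ValueError(
                f"variable {v!r}: integration order exceeds max_diff={max_diff}"
            )
    return IntegrationSummary(orders, max(orders.values()))


def simulate_cips_critical_values(
    N: int,
    T: int,
    deterministic: str = "constant",
    reps: int = 10_000,
    seed: int = 0,
    chunk: int = 2_000,
) -> dict[float, float]:
    """Simulate CIPS critical values under independent pure random walks.

    Uses the unaugmented (p = 0) CADF regression, the convention under
    which the reference tables are tabulated. Vectorized over replications.
    """
    rng = np.random.default_rng(seed)
    det_cols = 1 + (deterministic == "constant_trend")
    ncol = det_cols + 3
    lag_col = det_cols
    lo, hi = _TRUNC[deterministic]
    stats_out = np.empty(reps)
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        e = rng.standard_normal((b, N, T))
        y = np.cumsum(e, axis=2)
        ybar = y.mean(axis=1)  # b x T
        dy = np.diff(y, axis=2)  # b x N x (T-1)
        dybar = np.diff(ybar, axis=1)
        rows = T - 2
        X = np.empty((b, N, rows, ncol))
        X[..., 0] = 1.0
        if det_cols == 2:
            X[..., 1] = np.arange(rows, dtype=float)
        X[..., lag_col] = y[:, :, 1:-1]
        X[..., lag_col + 1] = ybar[:, None, 1:-1]
        X[..., lag_col + 2] = dybar[:, None, 1:]
        Y = dy[:, :, 1:]
        XtX = np.einsum("bnri,bnrj->bnij", X, X)
        Xty = np.einsum("bnri,bnr->bni", X, Y)
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        resid = Y - np.einsum("bnri,bni->bnr", X, beta)
        dof = rows - ncol
        s2 = np.einsum("bnr,bnr->bn", resid, resid) / dof
        diag = np.linalg.inv(XtX)[..., lag_col, lag_col]
        t = beta[..., lag_col] / np.sqrt(s2 * diag)
        t = np.clip(t, lo, hi)
        stats_out[done : done + b] = t.mean(axis=1)
        done += b
    return {
        lvl: float(np.quantile(stats_out, lvl)) for lvl in (0.01, 0.05, 0.10)
    }
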