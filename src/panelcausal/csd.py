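"""Cross-sectional dependence (CSD) tests and slope-homogeneity tests.

Implements the pre-estimation diagnostics used before heterogeneous panel
causality analysis:

* Breusch–Pagan LM, Pesaran scaled LM, Pesaran CD — all built from the
  pairwise Pearson correlations of unit-level residual series;
* the bias-adjusted LM test, which replaces the asymptotic moments of
  ``(T-k) * rho_ij**2`` with their exact normal-theory finite-sample mean
  and variance given each unit's OLS projection matrix;
* the Pesaran–Yamagata dispersion (delta) tests of slope homogeneity.

Conventions: LM-type statistics use upper-tail p-values, CD is two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import BalancedPanel

__all__ = [
    "CSDResult",
    "SlopeHomogeneityResult",
    "pairwise_correlations",
    "breusch_pagan_lm",
    "pesaran_scaled_lm",
    "pesaran_cd",
    "bias_adjusted_lm",
    "slope_homogeneity",
    "csd_report",
]


@dataclass(frozen=True)
class CSDResult:
    test_name: str  # one of {"BP_LM", "scaled_LM", "CD", "bias_adjusted_LM"}
    statistic: float
    p_value: float
    N: int
    T: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.test_name}: non-finite statistic")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.test_name}: p-value {self.p_value} outside [0,1]")


@dataclass(frozen=True)
class SlopeHomogeneityResult:
    """Pesaran–Yamagata delta tests. ``s_tilde`` is the weighted dispersion
    of unit slopes around the pooled (weighted fixed-effects) slope that both
    statistics standardize."""

    delta_tilde: float
    delta_tilde_adj: float
    s_tilde: float
    k: int
    p_values: tuple[float, float]  # (delta_tilde, delta_tilde_adj), upper tail


def pairwise_correlations(residual_matrix: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of the rows of an ``N x T`` matrix.

    Returns the full symmetric ``N x N`` correlation matrix (diagonal 1);
    consumers use the strict upper triangle. Raises on any zero-variance row.
    """
    r = np.asarray(residual_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need an N x T matrix with N >= 2")
    sd = r.std(axis=1)
    if np.any(sd == 0):
        i = int(np.argmax(sd == 0))
        raise ValueError(f"degenerate series: unit index {i} has zero variance")
    return np.corrcoef(r)


def _upper(corr: np.ndarray) -> np.ndarray:
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    return corr[iu]


def breusch_pagan_lm(corr: np.ndarray, T: int) -> CSDResult:
    """BP LM = T * sum_{i<j} rho_ij^2, chi-square with N(N-1)/2 df."""
    rho = _upper(corr)
    n = corr.shape[0]
    stat = float(T * np.sum(rho**2))
    df = n * (n - 1) // 2
    return CSDResult("BP_LM", stat, float(stats.chi2.sf(stat, df)), n, T)


def pesaran_scaled_lm(corr: np.ndarray, T: int) -> CSDResult:
    """Scaled LM = sqrt(1/(N(N-1))) * sum_{i<j} (T rho^2 - 1), upper-tail normal."""
    rho = _upper(corr)
    n = corr.shape[0]
    stat = float(np.sqrt(1.0 / (n * (n - 1))) * np.sum(T * rho**2 - 1.0))
    return CSDResult("scaled_LM", stat, float(stats.norm.sf(stat)), n, T)


def pesaran_cd(corr: np.ndarray, T: int) -> CSDResult:
    """CD = sqrt(2T/(N(N-1))) * sum_{i<j} rho_ij, two-sided normal."""
    rho = _upper(corr)
    n = corr.shape[0]
    stat = float(np.sqrt(2.0 * T / (n * (n - 1))) * np.sum(rho))
    return CSDResult("CD", stat, float(2 * stats.norm.sf(abs(stat))), n, T)


def bias_adjusted_lm(
    residuals: np.ndarray, design_matrices: list[np.ndarray] | np.ndarray
) -> CSDResult:
    """Bias-adjusted LM test from unit-wise OLS residuals.

    Parameters
    ----------
    residuals
        ``N x T`` matrix of OLS residuals (one row per unit, common sample).
    design_matrices
        Per-unit regressor matrices ``X_i`` of shape ``T x k`` (intercept
        included); a single shared matrix may be passed.

    Standardizes ``(T-k) rho_ij^2`` with its exact mean and variance under
    normal errors given the projection matrices ``M_i = I - X (X'X)^-1 X'``:
    mean ``tr(M_i M_j)/m`` and variance
    ``a1 * tr(M_i M_j)^2 + 2 a2 * tr((M_i M_j)^2)`` with ``m = T - k``,
    ``a2 = 3/(m+2)^2`` and ``a1 = a2 - 1/m^2``; then averages over pairs.
    """
    u = np.asarray(residuals, dtype=float)
    n, T = u.shape
    if n < 2:
        raise ValueError("need N >= 2")
    if isinstance(design_matrices, np.ndarray) and design_matrices.ndim == 2:
        design_matrices = [design_matrices] * n
    if len(design_matrices) != n:
        raise ValueError("one design matrix per unit required")
    k = design_matrices[0].shape[1]
    m = T - k
    if m <= 4:
        raise ValueError("T - k must exceed 4 for the variance correction")

    # projection complements M_i; T x T each, N of them
    Ms = []
    for X in design_matrices:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != T:
            raise ValueError("design matrix rows must match residual length")
        Q, _ = np.linalg.qr(X)
        Ms.append(np.eye(T) - Q @ Q.T)

    corr = pairwise_correlations(u)
    a2 = 3.0 / (m + 2) ** 2
    a1 = a2 - 1.0 / m**2

    total = 0.0
    for i in range(n - 1):
        Mi = Ms[i]
        for j in range(i + 1, n):
            P = Mi @ Ms[j]
            tr = np.trace(P)
            tr2 = float(np.sum(P * P.T))  # tr((M_i M_j)^2)
            mean_ij = tr / m
            var_ij = a1 * tr**2 + 2.0 * a2 * tr2
            total += (m * corr[i, j] ** 2 - mean_ij) / np.sqrt(var_ij)

    stat = float(np.sqrt(2.0 / (n * (n - 1))) * total)
    return CSDResult("bias_adjusted_LM", stat, float(stats.norm.sf(stat)), n, T)


# ---------------------------------------------------------------------------
# residual models for per-variable CSD testing
# ---------------------------------------------------------------------------

def residuals_for_csd(
    panel: BalancedPanel, variable: str, residual_model: str = "adf1"
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Unit-wise residuals used for per-variable CSD testing.

    ``adf1`` (default): residuals of the regression of ``dy_t`` on an
    intercept and ``y_{t-1}`` per unit — appropriate for trending or
    integrated series whose raw levels would produce degenerate
    correlations. ``level_demeaned``: within-unit demeaned levels
    (residuals of a constant-only regression).

    Returns the residual matrix and the per-unit design matrices (needed by
    the bias-adjusted LM test).
    """
    y = panel.matrix(variable)
    if residual_model == "level_demeaned":
        X = np.ones((panel.T, 1))
        return y - y.mean(axis=1, keepdims=True), [X] * panel.N
    if residual_model != "adf1":
        raise ValueError("residual_model must be 'adf1' or 'level_demeaned'")
    dy = np.diff(y, axis=1)  # N x (T-1)
    resid = np.empty_like(dy)
    designs = []
    for i in range(panel.N):
        X = np.column_stack([np.ones(panel.T - 1), y[i, :-1]])
        beta, *_ = np.linalg.lstsq(X, dy[i], rcond=None)
        resid[i] = dy[i] - X @ beta
        designs.append(X)
    return resid, designs


def csd_report(
    panel: BalancedPanel, variables: list[str] | None = None, residual_model: str = "adf1"
) -> dict[str, dict[str, CSDResult]]:
    """All four CSD tests for each variable, from the chosen residual model."""
    out: dict[str, dict[str, CSDResult]] = {}
    for v in variables or panel.variables:
        resid, designs = residuals_for_csd(panel, v, residual_model)
        corr = pairwise_correlations(resid)
        T = resid.shape[1]
        out[v] = {
            "BP_LM": breusch_pagan_lm(corr, T),
            "scaled_LM": pesaran_scaled_lm(corr, T),
            "CD": pesaran_cd(corr, T),
            "bias_adjusted_LM": bias_adjusted_lm(resid, designs),
        }
    return out


# ---------------------------------------------------------------------------
# Pesaran–Yamagata slope homogeneity
# ---------------------------------------------------------------------------

def slope_homogeneity(
    panel: BalancedPanel, dependent: str, regressors: list[str]
) -> SlopeHomogeneityResult:
    """Pesaran–Yamagata delta test of H0: identical slopes across units.

    Procedure (per unit, after within-unit demeaning to remove fixed
    effects): OLS slopes ``b_i``; a pooled weighted fixed-effects slope
    using the unit variance estimates from pooled-slope residuals; the
    dispersion ``S = sum_i (b_i - b_wfe)' (X_i' X_i / s2_i) (b_i - b_wfe)``;
    then

    ``delta_tilde     = sqrt(N) (S/N - k) / sqrt(2k)``
    ``delta_tilde_adj = sqrt(N) (S/N - E) / sqrt(Var)`` with ``E = k`` and
    ``Var = 2k(T-k-1)/(T+1)``.
    """
    k = len(regressors)
    if k < 1:
        raise ValueError("need at least one regressor")
    N, T = panel.N, panel.T
    if T <= k + 2:
        raise ValueError("need T > k + 2")

    y = panel.matrix(dependent)
    Xall = np.stack([panel.matrix(r) for r in regressors], axis=2)  # N x T x k
    yd = y - y.mean(axis=1, keepdims=True)
    Xd = Xall - Xall.mean(axis=1, keepdims=True)

    # unit-wise OLS slopes
    b_unit = np.empty((N, k))
    for i in range(N):
        XtX = Xd[i].T @ Xd[i]
        if np.linalg.matrix_rank(XtX) < k:
            raise np.linalg.LinAlgError(
                f"rank-deficient regressors for unit {panel.unit_ids[i]!r}"
            )
        b_unit[i] = np.linalg.solve(XtX, Xd[i].T @ yd[i])

    # pooled FE slope, then sigma~2_i from pooled-slope residuals
    XtX_sum = np.einsum("itk,itl->kl", Xd, Xd)
    Xty_sum = np.einsum("itk,it->k", Xd, yd)
    b_fe = np.linalg.solve(XtX_sum, Xty_sum)
    resid_pooled = yd - Xd @ b_fe
    s2 = np.sum(resid_pooled**2, axis=1) / (T - 1)
    if np.any(s2 <= 0):
        raise ValueError("zero residual variance under pooled slope")

    # weighted FE estimator with those variances
    XtX_w = np.einsum("itk,itl,i->kl", Xd, Xd, 1.0 / s2)
    Xty_w = np.einsum("itk,it,i->k", Xd, yd, 1.0 / s2)
    b_wfe = np.linalg.solve(XtX_w, Xty_w)

    dev = b_unit - b_wfe
    S = 0.0
    for i in range(N):
        S += dev[i] @ (Xd[i].T @ Xd[i]) @ dev[i] / s2[i]
    S = float(S)

    d_tilde = float(np.sqrt(N) * (S / N - k) / np.sqrt(2.0 * k))
    var_adj = 2.0 * k * (T - k - 1.0) / (T + 1.0)
    d_adj = float(np.sqrt(N) * (S / N - k) / np.sqrt(var_adj))
    return SlopeHomogeneityResult(
        delta_tilde=d_tilde,
        delta_tilde_adj=d_adj,
        s_tilde=S,
        k=k,
        p_values=(float(stats.norm.sf(d_tilde)), float(stats.norm.sf(d_adj))),
    )
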