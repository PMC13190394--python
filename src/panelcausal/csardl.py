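"""Cross-sectionally augmented ARDL (CS-ARDL) mean-group estimation.

Per unit, an ARDL(1,1,...,1) in levels is augmented with the current and
``pT`` lagged cross-sectional averages of the dependent variable and every
regressor, which proxy the unobserved common factors. Long-run coefficients
``theta_i = (b0 + b1) / (1 - phi_i)`` and the error-correction coefficient
``ect_i = -(1 - phi_i)`` follow algebraically; the mean-group (MG) panel
estimates are simple cross-unit averages with the nonparametric dispersion
standard error ``sqrt(sum (b_i - bbar)^2 / (N (N - 1)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import BalancedPanel

__all__ = ["CSARDLSpec", "CSARDLResult", "MGEstimate", "fit_cs_ardl", "ect_interpretation"]


@dataclass(frozen=True)
class CSARDLSpec:
    dependent: str
    regressors: tuple[str, ...]
    pT: int | None = None  # cross-average truncation lag; default floor(T**(1/3))
    p_lag: int = 1  # dependent-variable lag order (fixed at 1)
    q_lag: int = 1  # regressor lag order (fixed at 1)


@dataclass(frozen=True)
class MGEstimate:
    name: str
    mean: float
    se: float
    t: float
    p_value: float
    per_unit: tuple[float, ...]


@dataclass
class CSARDLResult:
    spec: CSARDLSpec
    long_run: dict[str, MGEstimate]
    short_run: dict[str, MGEstimate]  # differenced-form coefficients
    ect: MGEstimate
    n_units_used: int
    dropped_units: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ect_in_stable_range(self) -> bool:
        return -2.0 < self.ect.mean < 0.0


def _mg(name: str, values: np.ndarray) -> MGEstimate:
    n = values.size
    mean = float(values.mean())
    se = float(np.sqrt(np.sum((values - mean) ** 2) / (n * (n - 1))))
    t = mean / se if se > 0 else np.inf * np.sign(mean)
    p = float(2 * stats.norm.sf(abs(t)))
    return MGEstimate(name, mean, se, float(t), p, tuple(values))


def fit_cs_ardl(
    panel: BalancedPanel, spec: CSARDLSpec, form: str = "levels"
) -> CSARDLResult:
    """Fit the CS-ARDL(1,1,..) per unit and aggregate with the MG estimator.

    Per unit the levels regression is
    ``y_t = a + phi * y_{t-1} + sum_r (b0_r x_{r,t} + b1_r x_{r,t-1})
    + sum_{l=0..pT} d_l' zbar_{t-l} + e_t`` with ``zbar`` the cross-section
    averages of (y, x_1, ..). Units whose design is singular are dropped
    (MG over the remainder, error if fewer than 80% survive).

    ``form='ecm'`` fits the error-correction reparameterization
    ``dy_t = a + lam * y_{t-1} + sum_r (g_r dx_{r,t} + c_r x_{r,t-1}) + ...``
    instead; the two forms span the same column space, so long-run and
    error-correction estimates coincide exactly.
    """
    if form not in ("levels", "ecm"):
        raise ValueError("form must be 'levels' or 'ecm'")
    y = panel.matrix(spec.dependent)
    Xs = [panel.matrix(r) for r in spec.regressors]
    N, T = panel.N, panel.T
    nx = len(Xs)
    pT = spec.pT if spec.pT is not None else int(np.floor(T ** (1.0 / 3.0)))

    # pT = 0 disables the cross-average augmentation entirely (plain ARDL);
    # pT >= 1 includes average lags 0..pT.
    start = max(1, pT)
    Teff = T - start
    n_ca = (1 + nx) * (pT + 1) if pT > 0 else 0
    nparam = 1 + 1 + 2 * nx + n_ca
    if Teff - nparam < 3:
        raise ValueError(
            f"insufficient degrees of freedom: {Teff} obs, {nparam} parameters"
        )
    notes = []
    if T < 30:
        notes.append(
            f"T={T} is below the sample sizes where CS-ARDL performs optimally; "
            "treat results as supplementary"
        )

    ybar = y.mean(axis=0)
    xbars = [x.mean(axis=0) for x in Xs]

    phi = np.empty(N)
    b_sum = np.empty((N, nx))  # b0 + b1 per regressor
    b0 = np.empty((N, nx))
    ok = np.ones(N, dtype=bool)
    for i in range(N):
        cols = [np.ones(Teff), y[i, start - 1 : T - 1]]
        for x in Xs:
            if form == "levels":
                cols.append(x[i, start:T])
            else:
                cols.append(x[i, start:T] - x[i, start - 1 : T - 1])
            cols.append(x[i, start - 1 : T - 1])
        if pT > 0:
            for lag in range(pT + 1):
                cols.append(ybar[start - lag : T - lag])
                for xb in xbars:
                    cols.append(xb[start - lag : T - lag])
        Z = np.column_stack(cols)
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            ok[i] = False
            continue
        resp = y[i, start:T] if form == "levels" else y[i, start:T] - y[i, start - 1 : T - 1]
        beta, *_ = np.linalg.lstsq(Z, resp, rcond=None)
        phi[i] = beta[1] if form == "levels" else 1.0 + beta[1]
        for r in range(nx):
            b0[i, r] = beta[2 + 2 * r]
            if form == "levels":
                b_sum[i, r] = beta[2 + 2 * r] + beta[3 + 2 * r]
            else:
                b_sum[i, r] = beta[3 + 2 * r]
        if abs(1.0 - phi[i]) < 1e-10:
            ok[i] = False  # long-run coefficient undefined

    dropped = [panel.unit_ids[i] for i in range(N) if not ok[i]]
    kept = int(ok.sum())
    if kept < int(np.ceil(0.8 * N)):
        raise ValueError(
            f"only {kept}/{N} units estimable (dropped: {dropped}); "
            "MG requires at least 80% of units"
        )
    if dropped:
        notes.append(f"units dropped for singularity: {dropped}")

    theta = b_sum[ok] / (1.0 - phi[ok])[:, None]
    ect = -(1.0 - phi[ok])

    long_run = {
        r: _mg(r, theta[:, j]) for j, r in enumerate(spec.regressors)
    }
    short_run = {
        f"d_{r}": _mg(f"d_{r}", b0[ok][:, j]) for j, r in enumerate(spec.regressors)
    }
    result = CSARDLResult(
        spec=CSARDLSpec(spec.dependent, tuple(spec.regressors), pT),
        long_run=long_run,
        short_run=short_run,
        ect=_mg("ect", ect),
        n_units_used=kept,
        dropped_units=dropped,
        notes=notes,
    )
    if not result.ect_in_stable_range:
        result.notes.append(
            f"MG error-correction coefficient {result.ect.mean:.3f} outside (-2, 0)"
        )
    return result


def ect_interpretation(result: CSARDLResult | float) -> dict:
    """Adjustment-speed summary from the error-correction coefficient.

    A coefficient of -0.34 means 34% of any deviation from the long-run
    equilibrium is corrected each period, so equilibrium is restored in
    about ``ceil(1/0.34) = 3`` periods. Non-negative coefficients raise the
    ``no_stable_adjustment`` flag and no speed summary is produced.
    """
    ect = result.ect.mean if isinstance(result, CSARDLResult) else float(result)
    if ect >= 0:
        return {"ect": ect, "no_stable_adjustment": True}
    frac = abs(ect)
    return {
        "ect": ect,
        "no_stable_adjustment": False,
        "fraction_corrected_per_period": frac,
        "periods_to_equilibrium": int(np.ceil(1.0 / frac)),
    }
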