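"""Synthetic balanced panels with the statistical structure the analysis
assumes, plus the packaged fixture of printed country-level test results.

The generator emulates what an EU-style macro panel looks like to these
tests: integrated (I(1)) series, cross-sectional dependence through a
common factor with heterogeneous loadings, unit-specific dynamics,
optional planted Granger-causal links, and a sign-unrestricted
migration-like variable that can carry the five-year block-interpolation
smoothness artifact of published net-migration series.

Seeding is counter-based per (unit, variable) stream: enlarging ``N`` never
perturbs earlier units' draws, and a fixed seed reproduces the panel
bit-for-bit.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BalancedPanel

__all__ = [
    "CausalLink",
    "VariableDGP",
    "DGPConfig",
    "generate",
    "eu_like_config",
    "fixture_printed_tables",
    "fixture_fisher_statistics",
    "FIXTURE_PAIRS",
]

FIXTURE_PAIRS = [("co2", "migr"), ("hexp", "migr"), ("hexp", "co2")]


@dataclass(frozen=True)
class CausalLink:
    """Planted Granger-causal link: ``target_t += coef * source_{t-lag}``
    in the stationary innovations, applied to ``units`` (None = all)."""

    source: str
    target: str
    coef: float
    lag: int = 1
    units: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coef):
            raise ValueError("causal link coefficient must be finite")
        if self.lag < 1:
            raise ValueError("causal link lag must be >= 1")


@dataclass(frozen=True)
class VariableDGP:
    """Process for one variable: 'random_walk', 'ar1' or 'trend_stationary'."""

    process: str = "random_walk"
    rho: float = 0.5  # AR(1) coefficient (ar1 only)
    innovation_sd: float = 1.0
    trend: float = 0.1  # slope for trend_stationary
    migration_like: bool = False  # sign-unrestricted; may be block-interpolated
    block_window: int = 0  # e.g. 5 for five-year step interpolation

    def __post_init__(self) -> None:
        if self.process not in ("random_walk", "ar1", "trend_stationary"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.process == "ar1" and not abs(self.rho) < 1:
            raise ValueError("ar1 requires |rho| < 1")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")


@dataclass(frozen=True)
class DGPConfig:
    N: int = 27
    T: int = 21
    variables: dict[str, VariableDGP] = field(
        default_factory=lambda: {
            "co2": VariableDGP(),
            "hexp": VariableDGP(),
            "migr": VariableDGP(migration_like=True),
        }
    )
    factor_loading_range: tuple[float, float] = (0.5, 1.5)
    n_factors: int = 1  # 0 disables cross-sectional dependence
    causal_links: tuple[CausalLink, ...] = ()
    slope_heterogeneity_sd: float = 0.0  # jitter on per-unit AR coefficients
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2 or self.T < 10:
            raise ValueError(f"need N >= 2 and T >= 10, got N={self.N}, T={self.T}")
        for link in self.causal_links:
            for v in (link.source, link.target):
                if v not in self.variables:
                    raise ValueError(f"causal link references unknown variable {v!r}")


def eu_like_config(**overrides) -> DGPConfig:
    """The default study-shaped configuration: 27 units, 21 periods, all
    three variables I(1), one common factor with loadings U(0.5, 1.5)."""
    return DGPConfig(**overrides)


def generate(config: DGPConfig) -> BalancedPanel:
    """Generate a balanced panel from the configured data-generating process.

    Per unit i and variable v, the stationary innovation is
    ``e_vit = gamma_vi * f_vt + causal-link terms + eps_vit``; the series is
    then built by the variable's process (cumulated once for random walks,
    AR(1) recursion, or linear trend plus noise). Block interpolation for
    migration-like variables replaces each ``block_window``-period block by
    its within-block mean, mimicking the step artifact of five-year
    cumulative estimates.
    """
    N, T = config.N, config.T
    burn = 50  # burn-in so AR processes start near stationarity
    Tb = T + burn
    names = list(config.variables)

    # counter-based substreams: (seed, tag, unit, variable-index)
    def _rng(*key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((config.seed, *key)))

    # common factors per variable (AR(0.5) factor process)
    factors = {}
    for vi, v in enumerate(names):
        f = np.zeros(Tb)
        if config.n_factors > 0:
            e = _rng(1, 0, vi).standard_normal(Tb)
            for t in range(1, Tb):
                f[t] = 0.5 * f[t - 1] + e[t]
        factors[v] = f

    loadings = {
        v: _rng(2, 0, vi).uniform(*config.factor_loading_range, size=N)
        for vi, v in enumerate(names)
    }

    # idiosyncratic innovations
    innov = {
        v: np.stack(
            [
                _rng(3, i, vi).standard_normal(Tb) * config.variables[v].innovation_sd
                for i in range(N)
            ]
        )
        for vi, v in enumerate(names)
    }

    # stationary innovation layer: factor + idiosyncratic
    e = {
        v: loadings[v][:, None] * factors[v][None, :] + innov[v] for v in names
    }
    # planted causal links operate on the innovation layer so that the
    # integrated series inherit lagged dependence
    for link in config.causal_links:
        units = range(N) if link.units is None else link.units
        for i in units:
            e[link.target][i, link.lag:] += link.coef * e[link.source][i, : -link.lag]

    data: dict[str, np.ndarray] = {}
    for vi, v in enumerate(names):
        spec = config.variables[v]
        rho_i = np.full(N, spec.rho)
        if config.slope_heterogeneity_sd > 0:
            rho_i = rho_i + _rng(4, 0, vi).normal(
                0, config.slope_heterogeneity_sd, size=N
            )
            rho_i = np.clip(rho_i, -0.99, 0.99)
        if spec.process == "random_walk":
            y = np.cumsum(e[v], axis=1)
        elif spec.process == "ar1":
            y = np.zeros((N, Tb))
            for t in range(1, Tb):
                y[:, t] = rho_i * y[:, t - 1] + e[v][:, t]
        else:  # trend_stationary
            y = spec.trend * np.arange(Tb)[None, :] + e[v]
        y = y[:, burn:]
        if spec.migration_like and spec.block_window > 1:
            w = spec.block_window
            for b0 in range(0, T, w):
                blk = y[:, b0 : b0 + w]
                y[:, b0 : b0 + w] = blk.mean(axis=1, keepdims=True)
        data[v] = y

    units = [f"U{i + 1:02d}" for i in range(N)]
    periods = list(range(2000, 2000 + T))
    return BalancedPanel(units, periods, data)


# ---------------------------------------------------------------------------
# packaged fixture: the printed country-level test results
# ---------------------------------------------------------------------------

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("panelcausal.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def fixture_printed_tables() -> dict[str, dict[tuple[str, str], float]]:
    """The transcribed printed per-country p-values for all six directions.

    Returns ``{country: {(source, target): p_value}}`` for 27 countries.
    Values are printed, 3-decimal-rounded p-values (a ``0.000`` entry means
    p < 0.0005), suitable for threshold-based classification and for the
    Fisher-combination worked example.
    """
    df = _read_packaged("printed_pvalues.csv")
    out: dict[str, dict[tuple[str, str], float]] = {}
    for _, row in df.iterrows():
        src, tgt = row["direction"].split("->")
        out.setdefault(row["country"], {})[(src, tgt)] = float(row["p_value"])
    n_dir = {c: len(d) for c, d in out.items()}
    assert all(v == 6 for v in n_dir.values()) and len(out) == 27
    return out


def fixture_printed_statistics() -> dict[str, dict[tuple[str, str], float]]:
    """Printed per-country Wald statistics, same keying as the p-values."""
    df = _read_packaged("printed_pvalues.csv")
    out: dict[str, dict[tuple[str, str], float]] = {}
    for _, row in df.iterrows():
        src, tgt = row["direction"].split("->")
        out.setdefault(row["country"], {})[(src, tgt)] = float(row["statistic"])
    return out


def fixture_fisher_statistics() -> dict[tuple[str, str], float]:
    """Printed panel Fisher statistics per direction."""
    df = _read_packaged("printed_fisher.csv")
    return {
        tuple(row["direction"].split("->")): float(row["fisher_statistic"])
        for _, row in df.iterrows()
    }
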