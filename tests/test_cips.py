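import numpy as np
import pytest

from panelcausal import (
    BalancedPanel,
    cadf,
    cips,
    cips_critical_values,
    integration_order,
)


def _rw_panel(N, T, seed, drift=0.0):
    rng = np.random.default_rng(seed)
    y = np.cumsum(rng.normal(loc=drift, size=(N, T)), axis=1)
    return BalancedPanel([f"u{i}" for i in range(N)], list(range(T)), {"y": y})


def test_cips_is_mean_of_cadf(eu_like_panel):
    res = cips(eu_like_panel, "co2", p=1)
    assert res.cips == pytest.approx(
        np.mean([r.t_statistic for r in res.per_unit]), abs=1e-14
    )
    assert res.N == 27 and res.T == 21


def test_cadf_invariant_to_level_shift(rng):
    y = np.cumsum(rng.normal(size=50))
    ybar = np.cumsum(rng.normal(size=50))
    t1 = cadf(y, ybar, p=1).t_statistic
    t2 = cadf(y + 1000.0, ybar, p=1).t_statistic
    assert t1 == pytest.approx(t2, abs=1e-8)


def test_unit_equal_to_cross_average_is_collinear():
    rng = np.random.default_rng(1)
    y = np.cumsum(rng.normal(size=(2, 30)), axis=1)
    y[1] = y[0]  # N=2 with identical units: unit == cross average
    panel = BalancedPanel(["a", "b"], list(range(30)), {"y": y})
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        cips(panel, "y", p=0)


def test_white_noise_cadf_strongly_negative(rng):
    """A stationary white-noise series mean-reverts: the lagged-level
    t-ratio behaves like a deep ADF rejection."""
    stats = []
    for _ in range(20):
        y = rng.normal(size=100)
        ybar = rng.normal(size=100) * 0.01 + y.mean()
        stats.append(cadf(y, ybar, p=0).t_statistic)
    assert np.median(stats) < -2.5


def test_critical_values_interpolation_grid_point():
    """At an exact grid point the interpolation returns the tabulated value,
    and CVs are ordered 1% < 5% < 10%."""
    cv = cips_critical_values(27, 21, "constant")
    assert cv[0.01] < cv[0.05] < cv[0.10] < 0
    # off-grid query lies between the neighbouring rows
    lo = cips_critical_values(20, 21)[0.05]
    hi = cips_critical_values(27, 21)[0.05]
    mid = cips_critical_values(24, 21)[0.05]
    assert min(lo, hi) <= mid <= max(lo, hi)


def test_integration_order_random_walk_vs_stationary():
    """Random-walk panels classify I(1); stationary AR panels I(0); the
    panel dmax is the maximum across variables."""
    rng = np.random.default_rng(11)
    N, T = 27, 60
    rw = np.cumsum(rng.normal(size=(N, T)), axis=1)
    ar = np.empty((N, T))
    ar[:, 0] = rng.normal(size=N)
    for t in range(1, T):
        ar[:, t] = 0.3 * ar[:, t - 1] + rng.normal(size=N)
    panel = BalancedPanel(
        [f"u{i}" for i in range(N)], list(range(T)), {"rw": rw, "ar": ar}
    )
    summary = integration_order(panel, ["rw", "ar"], p=1)
    assert summary.orders["ar"] == 0
    assert summary.orders["rw"] == 1
    assert summary.dmax == 1


def test_integration_order_exceeding_max_diff_raises():
    rng = np.random.default_rng(5)
    N, T = 10, 40
    # double-integrated series: still non-stationary after one difference
    y = np.cumsum(np.cumsum(rng.normal(size=(N, T)), axis=1), axis=1)
    panel = BalancedPanel([f"u{i}" for i in range(N)], list(range(T)), {"y": y})
    with pytest.raises(ValueError, match="exceeds max_diff"):
        integration_order(panel, ["y"], max_diff=1, p=1)
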