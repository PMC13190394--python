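import numpy as np
import pytest

from panelcausal import (
    BalancedPanel,
    bias_adjusted_lm,
    breusch_pagan_lm,
    pairwise_correlations,
    pesaran_cd,
    pesaran_scaled_lm,
    slope_homogeneity,
)
from panelcausal.csd import csd_report


def test_pairwise_correlation_extremes(rng):
    base = rng.normal(size=6)
    m = np.vstack([base, base, -base])
    corr = pairwise_correlations(m)
    assert corr[0, 1] == pytest.approx(1.0)
    assert corr[0, 2] == pytest.approx(-1.0)


def test_pairwise_correlation_matches_hand_formula():
    m = np.array([[1, 4, 2, 8, 5, 7], [3, 1, 4, 1, 5, 9], [2, 7, 1, 8, 2, 8]], float)
    corr = pairwise_correlations(m)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = m[i] - m[i].mean(), m[j] - m[j].mean()
            expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
            assert corr[i, j] == pytest.approx(expected, rel=1e-12)


def test_zero_variance_row_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        pairwise_correlations(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


def test_bp_lm_closed_forms():
    zero = np.eye(4)
    r = breusch_pagan_lm(zero, T=10)
    assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    corr = np.array([[1.0, 0.5], [0.5, 1.0]])
    r = breusch_pagan_lm(corr, T=10)
    assert r.statistic == pytest.approx(10 * 0.25)  # T * rho^2, df = 1


def test_cd_zero_correlation():
    r = pesaran_cd(np.eye(5), T=20)
    assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)


def test_cd_and_scaled_lm_match_direct_formula(rng):
    m = rng.normal(size=(6, 40))
    corr = pairwise_correlations(m)
    iu = np.triu_indices(6, 1)
    rho = corr[iu]
    T, n = 40, 6
    assert pesaran_cd(corr, T).statistic == pytest.approx(
        np.sqrt(2 * T / (n * (n - 1))) * rho.sum(), rel=1e-12
    )
    assert pesaran_scaled_lm(corr, T).statistic == pytest.approx(
        np.sqrt(1 / (n * (n - 1))) * (T * rho**2 - 1).sum(), rel=1e-12
    )


def test_csd_statistics_scale_invariant(eu_like_panel):
    """Rescaling any unit's series by a positive constant (e.g. persons vs
    thousands of persons) leaves all correlation-based statistics unchanged."""
    rep1 = csd_report(eu_like_panel, ["migr"])["migr"]
    scaled = {v: eu_like_panel.matrix(v).copy() for v in eu_like_panel.variables}
    scaled["migr"][3] *= 1e6
    panel2 = BalancedPanel(eu_like_panel.unit_ids, eu_like_panel.periods, scaled)
    rep2 = csd_report(panel2, ["migr"])["migr"]
    for name in rep1:
        assert rep1[name].statistic == pytest.approx(rep2[name].statistic, rel=1e-9)


def test_bias_adjusted_lm_centered_under_null(rng):
    """Mean of the standardized pair terms should be ~0 for independent
    normal errors (single draw, generous tolerance)."""
    N, T, k = 8, 60, 2
    X = [np.column_stack([np.ones(T), rng.normal(size=(T, k - 1))]) for _ in range(N)]
    resid = []
    for Xi in X:
        y = rng.normal(size=T)
        b, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        resid.append(y - Xi @ b)
    r = bias_adjusted_lm(np.vstack(resid), X)
    assert abs(r.statistic) < 4.0
    assert 0 <= r.p_value <= 1


def test_slope_homogeneity_zero_dispersion():
    """Two units with identical data: S = 0 and delta < 0."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    y = 1.5 * x + rng.normal(size=20)
    panel = BalancedPanel(
        ["A", "B"], list(range(20)), {"y": np.vstack([y, y]), "x": np.vstack([x, x])}
    )
    res = slope_homogeneity(panel, "y", ["x"])
    assert res.s_tilde == pytest.approx(0.0, abs=1e-10)
    assert res.delta_tilde < 0 and res.delta_tilde_adj < 0


def test_slope_homogeneity_detects_heterogeneity(rng):
    N, T = 20, 40
    x = rng.normal(size=(N, T))
    betas = rng.normal(1.0, 0.8, size=N)
    y = betas[:, None] * x + rng.normal(size=(N, T))
    panel = BalancedPanel(
        [f"u{i}" for i in range(N)], list(range(T)), {"y": y, "x": x}
    )
    res = slope_homogeneity(panel, "y", ["x"])
    assert res.p_values[1] < 0.01
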