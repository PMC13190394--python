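import numpy as np
import pytest

from panelcausal import (
    CausalLink,
    DGPConfig,
    VariableDGP,
    bootstrap_panel_causality,
    fisher_combine,
    generate,
    lavar_wald,
    run_all_pairs,
    select_lag_aic,
)
from panelcausal.ek import _rebuild, _restricted_fit


# ---------------------------------------------------------------------------
# lag selection
# ---------------------------------------------------------------------------

def test_kmax_one_degenerate_search():
    rng = np.random.default_rng(0)
    y, x = rng.normal(size=(2, 60))
    assert select_lag_aic(y, x, k_max=1) == 1


def test_aic_prefers_one_lag_for_white_noise(rng):
    picks = [
        select_lag_aic(rng.normal(size=200), rng.normal(size=200), k_max=3)
        for _ in range(30)
    ]
    assert np.mean(np.array(picks) == 1) > 0.6


def test_aic_recovers_var2(rng):
    """Data from a VAR(2) with strong second-lag coefficients."""
    picks = []
    for _ in range(20):
        T = 200
        y = np.zeros((2, T))
        for t in range(2, T):
            y[0, t] = 0.2 * y[0, t - 1] + 0.55 * y[1, t - 2] + rng.normal()
            y[1, t] = 0.2 * y[1, t - 1] + 0.55 * y[0, t - 2] + rng.normal()
        picks.append(select_lag_aic(y[0], y[1], k_max=3))
    assert np.mean(np.array(picks) == 2) > 0.6


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def test_constant_source_is_singular(rng):
    y = np.cumsum(rng.normal(size=60))
    with pytest.raises(np.linalg.LinAlgError):
        lavar_wald(y, np.zeros(60), k=1, dmax=1)


def test_wald_invariant_to_source_rescaling(rng):
    y = np.cumsum(rng.normal(size=80))
    x = np.cumsum(rng.normal(size=80))
    w1 = lavar_wald(y, x, k=2, dmax=1).wald
    w2 = lavar_wald(y, x * 1e6, k=2, dmax=1).wald
    assert w1 == pytest.approx(w2, rel=1e-10)


def test_wald_matches_statsmodels(rng):
    """Independent cross-check: the same joint restriction tested through
    statsmodels OLS on the identical design matrix."""
    sm = pytest.importorskip("statsmodels.api")
    y = np.cumsum(rng.normal(size=70))
    x = np.cumsum(rng.normal(size=70))
    k, dmax = 2, 1
    res = lavar_wald(y, x, k, dmax)
    P = k + dmax
    rows = 70 - P
    X = np.column_stack(
        [np.ones(rows)]
        + [y[P - j : 70 - j] for j in range(1, P + 1)]
        + [x[P - j : 70 - j] for j in range(1, P + 1)]
    )
    fit = sm.OLS(y[P:], X).fit()
    R = np.zeros((k, X.shape[1]))
    R[0, 1 + P] = 1.0
    R[1, 1 + P + 1] = 1.0
    w = fit.wald_test(R, use_f=False, scalar=True)
    assert res.wald == pytest.approx(float(w.statistic), rel=1e-8)


# ---------------------------------------------------------------------------
# Fisher combination
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pvals,expected",
    [([1.0, 1.0, 1.0], 0.0), ([np.exp(-1)], 2.0), ([np.exp(-2), np.exp(-3)], 10.0)],
)
def test_fisher_closed_forms(pvals, expected):
    assert fisher_combine(pvals) == pytest.approx(expected, abs=1e-12)


def test_fisher_empty_rejected():
    with pytest.raises(ValueError):
        fisher_combine([])


def test_fisher_zero_floored():
    lam = fisher_combine([0.0, 0.5])
    assert np.isfinite(lam)
    assert lam == pytest.approx(-2 * (np.log(1e-16) + np.log(0.5)))


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def _small_null_panel(seed=3, N=6, T=40):
    cfg = DGPConfig(
        N=N, T=T,
        variables={"y": VariableDGP(), "x": VariableDGP()},
        seed=seed,
    )
    return generate(cfg)


def test_rebuild_inverts_restricted_fit():
    """Feeding the (uncentered) restricted residuals back through the
    recursion reproduces the observed series exactly."""
    panel = _small_null_panel()
    y = panel.matrix("y")[0]
    x = panel.matrix("x")[0]
    k, dmax = 2, 1
    start = k + dmax
    beta, resid = _restricted_fit(y, x, k, dmax, start)
    rebuilt = _rebuild(y, x, beta, k, dmax, start, resid)
    np.testing.assert_allclose(rebuilt, y, rtol=1e-9)


def test_bootstrap_is_deterministic_given_seed():
    panel = _small_null_panel()
    r1 = bootstrap_panel_causality(panel, ("x", "y"), ("x", "y"), B=100, seed=11)
    r2 = bootstrap_panel_causality(panel, ("x", "y"), ("x", "y"), B=100, seed=11)
    assert r1.fisher_lambda == r2.fisher_lambda
    assert r1.bootstrap_p == r2.bootstrap_p


def test_lambda_internally_consistent():
    panel = _small_null_panel(seed=8)
    res = bootstrap_panel_causality(panel, ("x", "y"), ("x", "y"), B=100, seed=1)
    lam = -2 * np.sum(np.log([r.p_value for r in res.per_country]))
    assert res.fisher_lambda == pytest.approx(lam, abs=1e-12)
    assert res.bootstrap_p is not None and 0 < res.bootstrap_p <= 1


@pytest.fixture(scope="module")
def all_pairs_results():
    from panelcausal import DGPConfig, generate

    panel = generate(DGPConfig(seed=7))
    return run_all_pairs(panel, ("co2", "hexp", "migr"), B=100, seed=5)


def test_run_all_pairs_schema(all_pairs_results):
    results = all_pairs_results
    assert len(results) == 6
    directions = {r.direction for r in results}
    assert ("co2", "hexp") in directions and ("migr", "co2") in directions
    for r in results:
        assert len(r.per_country) == 27
        assert r.fisher_lambda >= 0
        # N >= T caveat surfaced for the study-shaped panel
        assert any("N >=" in n or "N=" in n for n in r.notes)


def test_pair_lag_orders_shared_between_directions(all_pairs_results):
    by_dir = {r.direction: r for r in all_pairs_results}
    fwd = by_dir[("co2", "hexp")]
    rev = by_dir[("hexp", "co2")]
    assert [r.k_i for r in fwd.per_country] == [r.k_i for r in rev.per_country]
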