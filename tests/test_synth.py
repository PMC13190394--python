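import numpy as np
import pytest

from panelcausal import CausalLink, DGPConfig, VariableDGP, generate
from panelcausal.synth import fixture_fisher_statistics, fixture_printed_tables


def test_same_seed_bit_identical():
    a = generate(DGPConfig(seed=42))
    b = generate(DGPConfig(seed=42))
    for v in a.variables:
        np.testing.assert_array_equal(a.matrix(v), b.matrix(v))


def test_enlarging_n_preserves_earlier_units():
    small = generate(DGPConfig(N=5, T=21, seed=9))
    big = generate(DGPConfig(N=8, T=21, seed=9))
    # idiosyncratic streams are per-unit; only the factor loadings draw
    # depends on N, so compare the de-loaded innovations via the seeds:
    # here we check the weaker but meaningful contract that unit labels and
    # periods align and the generator accepts growing N.
    assert big.unit_ids[:5] == small.unit_ids
    assert big.periods == small.periods


def test_block_interpolated_migration_is_piecewise_constant():
    cfg = DGPConfig(
        N=4, T=20, seed=1,
        variables={"migr": VariableDGP(migration_like=True, block_window=5)},
    )
    m = generate(cfg).matrix("migr")
    for b0 in range(0, 20, 5):
        blk = m[:, b0 : b0 + 5]
        np.testing.assert_allclose(blk, np.broadcast_to(blk[:, [0]], blk.shape))


def test_interpolation_inflates_autocorrelation():
    """Block-interpolated migration-like series are smoother: average lag-1
    autocorrelation of differences exceeds the uninterpolated counterpart."""
    def mean_ac1(block_window, seeds):
        acs = []
        for s in seeds:
            cfg = DGPConfig(
                N=5, T=20, seed=s,
                variables={"m": VariableDGP(migration_like=True, block_window=block_window)},
            )
            y = generate(cfg).matrix("m")
            for row in y:
                d = row - row.mean()
                acs.append((d[:-1] @ d[1:]) / (d @ d))
        return np.mean(acs)

    seeds = range(100)
    assert mean_ac1(5, seeds) > mean_ac1(0, seeds)


def test_planted_link_shows_in_innovations():
    cfg = DGPConfig(
        N=6, T=60, seed=3,
        variables={"migr": VariableDGP(), "co2": VariableDGP()},
        causal_links=(CausalLink("migr", "co2", coef=0.9, lag=1),),
        n_factors=0,
    )
    panel = generate(cfg)
    dm = np.diff(panel.matrix("migr"), axis=1)
    dc = np.diff(panel.matrix("co2"), axis=1)
    # lagged cross-correlation in the planted direction is strong
    cors = [np.corrcoef(dm[i, :-1], dc[i, 1:])[0, 1] for i in range(6)]
    assert np.mean(cors) > 0.4


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        (dict(N=1), "N >= 2"),
        (dict(T=5), "T >= 10"),
    ],
)
def test_invalid_config_rejected(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        DGPConfig(**kwargs)


def test_invalid_link_fields_named():
    with pytest.raises(ValueError, match="lag"):
        CausalLink("a", "b", 0.5, lag=0)
    with pytest.raises(ValueError, match="unknown variable"):
        DGPConfig(causal_links=(CausalLink("nope", "co2", 0.5),))


def test_fixture_shape_and_values():
    pv = fixture_printed_tables()
    assert len(pv) == 27
    assert all(len(d) == 6 for d in pv.values())
    assert pv["Italy"][("co2", "migr")] == 0.002
    assert all(p > 0.10 for p in pv["Netherlands"].values())
    fisher = fixture_fisher_statistics()
    assert fisher[("hexp", "migr")] == 90.565
    assert len(fisher) == 6
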