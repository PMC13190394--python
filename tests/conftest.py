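import numpy as np
import pytest

from panelcausal import BalancedPanel, DGPConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng) -> BalancedPanel:
    """2 units x 5 periods x 3 variables with hand-set values."""
    data = {
        "co2": np.array([[1.0, 3.0, 6.0, 6.5, 7.0], [2.0, 2.0, 2.0, 2.0, 2.0]]),
        "hexp": rng.normal(size=(2, 5)),
        "migr": rng.normal(scale=1e5, size=(2, 5)),  # sign-unrestricted scale
    }
    return BalancedPanel(["A", "B"], [2000, 2001, 2002, 2003, 2004], data)


@pytest.fixture
def eu_like_panel() -> BalancedPanel:
    """Default study-shaped synthetic panel: N=27, T=21, I(1), one factor."""
    return generate(DGPConfig(seed=7))
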