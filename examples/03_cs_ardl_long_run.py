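"""Long-run magnitudes with the CS-ARDL mean-group estimator.

The causality test says which variable precedes which; the CS-ARDL fit says
by how much in the long run, and how fast deviations from the long-run
relationship die out (the error-correction coefficient).
"""

import numpy as np

from panelcausal import BalancedPanel, CSARDLSpec, ect_interpretation, fit_cs_ardl

# homogeneous ARDL world: y_it = 0.5 y_{i,t-1} + 0.3 x_it + noise
# -> true long-run coefficient 0.3 / (1 - 0.5) = 0.6, error correction -0.5
rng = np.random.default_rng(3)
N, T = 27, 100
x = np.cumsum(rng.standard_normal((N, T)), axis=1)
y = np.zeros((N, T))
for t in range(1, T):
    y[:, t] = 0.5 * y[:, t - 1] + 0.3 * x[:, t] + rng.standard_normal(N)
panel = BalancedPanel([f"c{i}" for i in range(N)], list(range(T)), {"y": y, "x": x})

fit = fit_cs_ardl(panel, CSARDLSpec("y", ("x",)))
lr = fit.long_run["x"]
print(f"MG long-run coefficient: {lr.mean:.3f} (se {lr.se:.3f}, p {lr.p_value:.4f})")
print(f"ECT(-1): {fit.ect.mean:.3f} (se {fit.ect.se:.3f}, p {fit.ect.p_value:.4f})")

s = ect_interpretation(fit)
print(
    f"adjustment: {100 * s['fraction_corrected_per_period']:.0f}% of any deviation "
    f"corrected per period -> equilibrium in ~{s['periods_to_equilibrium']} periods"
)
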