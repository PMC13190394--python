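"""Simulated CIPS critical-value tables.

Each entry is the 1/5/10% quantile of the CIPS statistic under
independent pure random walks (unaugmented CADF regressions,
100 000 Monte Carlo replications per (N, T) point; generator
seed 20260924). Reproduce any entry with
:func:`panelcausal.cips.simulate_cips_critical_values`.
"""

N_GRID = (10, 15, 20, 27, 30, 50)
T_GRID = (15, 21, 30, 50, 100)

CV_TABLES = {
    'constant': {
        0.01: [
            [-2.6712, -2.6029, -2.566, -2.5439, -2.5428],
            [-2.5273, -2.4664, -2.4425, -2.4294, -2.4262],
            [-2.4395, -2.3945, -2.3718, -2.3641, -2.3599],
            [-2.3741, -2.3361, -2.3226, -2.3113, -2.3075],
            [-2.3543, -2.3135, -2.2996, -2.2942, -2.2894],
            [-2.2759, -2.2424, -2.2349, -2.2298, -2.229],
        ],
        0.05: [
            [-2.3818, -2.3485, -2.3333, -2.3249, -2.3271],
            [-2.281, -2.255, -2.2484, -2.2467, -2.2455],
            [-2.2258, -2.2073, -2.203, -2.1997, -2.2027],
            [-2.178, -2.1678, -2.1634, -2.1647, -2.168],
            [-2.1657, -2.1535, -2.1519, -2.1533, -2.1564],
            [-2.1153, -2.1053, -2.1074, -2.1134, -2.1155],
        ],
        0.1: [
            [-2.2282, -2.2123, -2.2069, -2.2057, -2.2104],
            [-2.153, -2.1437, -2.1417, -2.1451, -2.1478],
            [-2.1117, -2.1035, -2.1072, -2.1095, -2.1155],
            [-2.0781, -2.075, -2.0768, -2.082, -2.0883],
            [-2.0666, -2.0653, -2.0688, -2.0735, -2.0775],
            [-2.028, -2.03, -2.036, -2.0433, -2.0479],
        ],
    },
    'constant_trend': {
        0.01: [
            [-3.2413, -3.1412, -3.0849, -3.0532, -3.0336],
            [-3.0872, -2.9961, -2.957, -2.9295, -2.9173],
            [-3.0038, -2.9212, -2.8836, -2.8574, -2.8516],
            [-2.9202, -2.8586, -2.8213, -2.7983, -2.7911],
            [-2.9122, -2.833, -2.8034, -2.7824, -2.7748],
            [-2.8247, -2.7559, -2.7273, -2.713, -2.7105],
        ],
        0.05: [
            [-2.9368, -2.878, -2.8538, -2.8392, -2.8336],
            [-2.826, -2.7807, -2.7622, -2.7539, -2.7491],
            [-2.7696, -2.7276, -2.7145, -2.7071, -2.7055],
            [-2.718, -2.6843, -2.6722, -2.6639, -2.6652],
            [-2.7059, -2.669, -2.6568, -2.6513, -2.6531],
            [-2.646, -2.6167, -2.6068, -2.6055, -2.6077],
        ],
        0.1: [
            [-2.7731, -2.7421, -2.7314, -2.7261, -2.7259],
            [-2.6922, -2.6649, -2.6616, -2.6607, -2.6606],
            [-2.6478, -2.6262, -2.6231, -2.6232, -2.6268],
            [-2.6102, -2.5953, -2.5911, -2.591, -2.5965],
            [-2.5988, -2.5813, -2.5807, -2.5822, -2.5864],
            [-2.5541, -2.5431, -2.5421, -2.5455, -2.55],
        ],
    },
}
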