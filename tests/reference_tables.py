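"""Reference fitted weight tables from the original Shenyang land-use study.

Transcribed land-use blocks (six feature rows, five accident-characteristic
columns) of the four reported weight matrices, together with their printed
"Sum" rows. Printed entries are rounded to two decimals, so a recomputed
column total can differ from the printed Sum entry by up to 0.01; the exact
matches are flagged in ``EXACT_SUM`` below.

Used only to verify the weight-summary layout and Sum-row arithmetic; the
underlying dataset is not public, so these numbers are a fixed reference,
not a reproduction target.
"""

import numpy as np

FEATURES = (
    "plot_ratio",
    "poi_types",
    "centrality",
    "dist_cbd",
    "road_sections",
    "congestion_ratio",
)
CHARACTERISTICS = ("count", "date_to_winter", "time_to_1500", "isolation", "cross_section")

# rows: FEATURES; columns: CHARACTERISTICS
W_C_BLOCK = np.array(
    [
        [-0.39, 0.13, 0.09, 0.00, -0.49],
        [-0.12, 0.32, 0.37, 0.25, -0.27],
        [-0.12, 0.22, 0.32, -0.28, 0.04],
        [0.41, -0.24, 0.30, 0.19, 0.49],
        [-0.49, 0.39, 0.08, 0.04, -0.57],
        [1.02, 2.11, -0.73, 1.66, 0.21],
    ]
)
W_C_SUM = np.array([0.31, 2.93, 0.42, 1.86, -0.59])

W_I_BLOCK = np.array(
    [
        [0.19, 0.09, -0.03, 0.31, 0.27],
        [0.00, -0.27, 0.01, 0.07, -0.99],
        [0.03, 0.34, 0.16, -0.26, 0.64],
        [0.71, -0.85, 1.09, -0.50, 1.61],
        [-0.01, 0.13, -0.03, 0.13, -0.23],
        [-1.34, 3.24, 0.62, 1.15, -2.05],
    ]
)
W_I_SUM = np.array([-0.43, 2.69, 1.82, 0.89, -0.74])

W_F12_BLOCK = np.array(
    [
        [-0.43, -0.26, -0.35, 0.90, -0.05],
        [0.04, 0.02, 0.39, 0.99, -0.15],
        [-0.87, 0.72, -0.18, -1.35, -0.48],
        [0.22, 0.13, 0.01, -0.95, -0.36],
        [0.01, 0.60, 0.15, -0.71, 0.17],
        [-1.55, -0.14, -0.86, 4.15, -0.10],
    ]
)
W_F12_SUM = np.array([-2.58, 1.08, -0.84, 3.04, -0.97])

W_O_BLOCK = np.array(
    [
        [0.08, 0.23, 0.21, -0.05, -0.29],
        [-0.13, -0.01, 0.16, -0.15, 0.13],
        [-0.17, 0.01, -0.42, 0.44, -0.35],
        [0.20, 0.09, -0.70, -1.07, 0.64],
        [0.39, 0.03, -0.38, 0.15, -0.47],
        [0.27, -0.29, -0.42, -0.26, -0.16],
    ]
)
W_O_SUM = np.array([0.64, 0.06, -1.55, -0.94, -0.50])

TABLES = {
    "W_C": (W_C_BLOCK, W_C_SUM),
    "W_i": (W_I_BLOCK, W_I_SUM),
    "W_f1&2": (W_F12_BLOCK, W_F12_SUM),
    "W_o": (W_O_BLOCK, W_O_SUM),
}

#: (table, column index) pairs whose printed Sum entry equals the exact
#: column total of the printed block (13 of 20; the other 7 differ by 0.01
#: through rounding).
EXACT_SUM = {
    "W_C": (0, 1, 3, 4),
    "W_i": (2,),
    "W_f1&2": (0, 2, 4),
    "W_o": (0, 1, 2, 3, 4),
}
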