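"""Three-level interpretation of a fitted grid recurrence.

1. **Potential maps** — the latent state C of every cell, one raster per
   accident characteristic: the propensity of that characteristic before
   the output gate converts it to the observed value.
2. **Cell and regional reports** — the intermediate variables (input gate i,
   candidate state S, directional forget gates f1/f2, output gate o) of a
   single cell, read as proportions of local vs. neighbouring influence, and
   their volatility over a contiguous batch of windows.
3. **Weight summaries** — the land-use block (first six rows) of each weight
   matrix with a Sum row of column totals, plus the combined forget matrix
   W_f1&2 = W_f1 + W_f2; these are the area-wide rules of how each land-use
   property drives each characteristic's potential.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import MDLSTMParams, StateField
from .raster import ACCIDENT_CHANNELS, LAND_USE_CHANNELS, ScalingParams

__all__ = [
    "potential_maps",
    "cell_report",
    "regional_volatility",
    "weight_summary",
]

#: Rows of a cell report, in display order.
REPORT_VARIABLES = ("i", "S", "f1", "f2", "o")


def potential_maps(
    field: StateField,
    scaling_params: ScalingParams | None = None,
    unscale: bool = False,
    channels: tuple[str, ...] = ACCIDENT_CHANNELS,
) -> dict[str, np.ndarray]:
    """One raster per accident characteristic, extracted from the latent
    state C of a full-grid forward pass.

    By default maps are in the model's internal scale (C is a latent sum and
    not bounded to [0, 1]). With ``unscale=True`` the stored min-max
    parameters map each channel back to natural units — a labelled
    convenience view, not a statement that C lies in the target range.
    """
    C = field.C
    if C.shape[-1] != len(channels):
        raise ValueError("channel-name count does not match the state width")
    maps = {}
    for k, name in enumerate(channels):
        m = C[..., k].copy()
        if unscale:
            if scaling_params is None:
                raise ValueError("scaling_params required for the unscaled view")
            lo, hi = scaling_params[name]
            m = m * (hi - lo) + lo
        maps[name] = m
    return maps


def cell_report(
    field: StateField,
    t: int,
    s: int,
    channels: tuple[str, ...] = ACCIDENT_CHANNELS,
) -> pd.DataFrame:
    """Intermediate variables of cell (t, s): rows i, S, f1, f2, o, columns
    the accident characteristics. Values are direct reads of the state field
    (no recomputation)."""
    rows_n, cols_n = field.h.shape[:2]
    if not (0 <= t < rows_n and 0 <= s < cols_n):
        raise IndexError(f"cell ({t}, {s}) outside a {rows_n}x{cols_n} grid")
    data = {v: getattr(field, v)[t, s] for v in REPORT_VARIABLES}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(channels))


def regional_volatility(
    fields: list[StateField],
    reference_cell: tuple[int, int] | None = None,
    channels: tuple[str, ...] = ACCIDENT_CHANNELS,
) -> pd.DataFrame:
    """Spread of the intermediate variables across a batch of windows.

    For every variable element (variable x characteristic) the mean,
    standard deviation, min and max are taken across the batch at the
    reference cell (default: the window centre). Small standard deviations
    mean the gating behaviour is regionally stable.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 windows to summarize volatility")
    rows_n, cols_n = fields[0].h.shape[:2]
    if reference_cell is None:
        reference_cell = (rows_n // 2, cols_n // 2)
    t, s = reference_cell
    records = []
    for var in REPORT_VARIABLES:
        stack = np.stack([getattr(f, var)[t, s] for f in fields])  # (n_windows, d_h)
        for k, ch in enumerate(channels):
            v = stack[:, k]
            records.append(
                {
                    "variable": var,
                    "characteristic": ch,
                    "mean": float(v.mean()),
                    "std": float(v.std(ddof=0)),
                    "min": float(v.min()),
                    "max": float(v.max()),
                }
            )
    return pd.DataFrame.from_records(records)


def weight_summary(
    p: MDLSTMParams,
    feature_names: tuple[str, ...] = LAND_USE_CHANNELS,
    channels: tuple[str, ...] = ACCIDENT_CHANNELS,
) -> dict[str, pd.DataFrame]:
    """Land-use block of each weight matrix with a Sum row.

    Returns tables for W_C, W_i, W_f1&2 (the elementwise sum of the two
    directional forget matrices) and W_o: rows are the six land-use
    properties plus "Sum" (column totals), columns the five accident
    characteristics. Only the first d_x rows are displayed; the recurrent
    rows stay available on the parameter object.
    """
    if len(feature_names) != p.d_x:
        raise ValueError(f"need {p.d_x} feature names, got {len(feature_names)}")
    blocks = {
        "W_C": p.W_C[: p.d_x],
        "W_i": p.W_i[: p.d_x],
        "W_f1&2": p.W_f1[: p.d_x] + p.W_f2[: p.d_x],
        "W_o": p.W_o[: p.d_x],
    }
    out = {}
    for name, block in blocks.items():
        df = pd.DataFrame(block, index=list(feature_names), columns=list(channels))
        df.loc["Sum"] = df.sum(axis=0)
        out[name] = df
    return out
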