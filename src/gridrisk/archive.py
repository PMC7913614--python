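"""On-disk formats: raster archives, parameter archives, window sets.

A *raster archive* is a directory holding ``header.json`` (grid geometry,
channel names, optional scaling parameters) plus one whitespace-delimited
text matrix per channel and one for the observation mask. Text matrices are
written with 17 significant digits so a reload is bit-exact; the format
stays trivially convertible to GIS rasters without pulling in a GIS stack.

Parameters are a single JSON document (dimensions, channel names, the five
weight matrices and five biases as nested lists, plus any scaling/config
metadata). Window sets use a compressed ``.npz`` (they are bulky run-time
artifacts, not reports).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .model import MDLSTMParams
from .raster import (
    ACCIDENT_CHANNELS,
    LAND_USE_CHANNELS,
    AccidentGrid,
    GridSpec,
    LandUseGrid,
    WindowSet,
)

__all__ = [
    "save_grid",
    "load_grid",
    "save_params",
    "load_params",
    "save_windows",
    "load_windows",
]

_FMT = "%.17g"


def save_grid(path: str | Path, grid, scaling: dict | None = None) -> None:
    """Write a land-use or accident grid as a raster archive directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kind = "landuse" if isinstance(grid, LandUseGrid) else "accidents"
    header = {
        "kind": kind,
        "rows": grid.spec.rows,
        "cols": grid.spec.cols,
        "origin": list(grid.spec.origin),
        "cell_size": list(grid.spec.cell_size),
        "channels": list(grid.channels),
        "scaling": scaling,
    }
    (path / "header.json").write_text(json.dumps(header, indent=2))
    for k, name in enumerate(grid.channels):
        np.savetxt(path / f"{name}.txt", grid.values[:, :, k], fmt=_FMT)
    np.savetxt(path / "mask.txt", grid.mask.astype(int), fmt="%d")


def load_grid(path: str | Path):
    """Read a raster archive; returns (grid, scaling-or-None)."""
    path = Path(path)
    header = json.loads((path / "header.json").read_text())
    spec = GridSpec(
        rows=header["rows"],
        cols=header["cols"],
        origin=tuple(header["origin"]),
        cell_size=tuple(header["cell_size"]),
    )
    channels = tuple(header["channels"])
    values = np.stack(
        [np.loadtxt(path / f"{name}.txt").reshape(spec.rows, spec.cols) for name in channels],
        axis=-1,
    )
    mask = np.loadtxt(path / "mask.txt").reshape(spec.rows, spec.cols).astype(bool)
    cls = LandUseGrid if header["kind"] == "landuse" else AccidentGrid
    grid = cls(spec=spec, values=values, mask=mask, channels=channels)
    scaling = header.get("scaling")
    if scaling is not None:
        scaling = {k: tuple(v) for k, v in scaling.items()}
    return grid, scaling


def save_params(path: str | Path, p: MDLSTMParams, meta: dict | None = None) -> None:
    """Write a parameter archive (single JSON document)."""
    doc = {
        "d_x": p.d_x,
        "d_h": p.d_h,
        "input_channels": list(LAND_USE_CHANNELS)[: p.d_x],
        "output_channels": list(ACCIDENT_CHANNELS)[: p.d_h],
        "weights": {n: getattr(p, n).tolist() for n in p.MATRIX_NAMES},
        "biases": {n: getattr(p, n).tolist() for n in p.BIAS_NAMES},
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_params(path: str | Path) -> tuple[MDLSTMParams, dict]:
    doc = json.loads(Path(path).read_text())
    kwargs = {n: np.asarray(doc["weights"][n], dtype=float) for n in MDLSTMParams.MATRIX_NAMES}
    kwargs |= {n: np.asarray(doc["biases"][n], dtype=float) for n in MDLSTMParams.BIAS_NAMES}
    return MDLSTMParams(**kwargs), doc.get("meta", {})


def save_windows(path: str | Path, ws: WindowSet) -> None:
    np.savez_compressed(
        path,
        inputs=ws.inputs,
        targets=ws.targets,
        masks=ws.masks,
        anchors=ws.anchors,
        usable=ws.usable,
        split=ws.split.astype(str),
        size=ws.size,
        stride=ws.stride,
        scaling=json.dumps(ws.scaling_params),
    )


def load_windows(path: str | Path) -> WindowSet:
    with np.load(path, allow_pickle=False) as z:
        scaling = json.loads(str(z["scaling"]))
        if scaling is not None:
            scaling = {
                grp: {k: tuple(v) for k, v in params.items()} for grp, params in scaling.items()
            }
        return WindowSet(
            inputs=z["inputs"],
            targets=z["targets"],
            masks=z["masks"],
            anchors=z["anchors"],
            usable=z["usable"],
            size=int(z["size"]),
            stride=int(z["stride"]),
            split=z["split"].astype(object),
            scaling_params=scaling,
        )
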