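"""Encoding, rasterization, scaling and window sampling.

This module turns raw injury-accident records and land-use attributes into
the aligned raster pair the model consumes:

* accident *characteristics* are encoded to numeric indicators whose
  relationship to accident frequency is (approximately) linear: calendar
  dates become day-distance to the nearest winter solstice (22 December,
  the seasonal accident peak in a cold-climate city), clock times become
  second-distance to 15:00 (the afternoon accident peak), and the two
  road-layout labels become ordinal levels;
* events are aggregated to a grid of ~400 m x 444 m cells, counting events
  within 3000 m of each cell centre and averaging the encoded
  characteristics over those events;
* channels are min-max scaled to [0, 1];
* overlapping size x size windows (default 9 x 9) are cut for training,
  discarding windows in which at least 80% of the cells carry no accident
  information, and a fixed-size random test set (default 100 windows) is
  held out.

Channel order is a package-wide contract: ``LAND_USE_CHANNELS`` defines the
rows of every weight-matrix summary and ``ACCIDENT_CHANNELS`` the columns.
Cells are indexed 0-based, row-major: cell (t, s) is row t, column s, and its
centre sits at ``origin + ((s + 0.5) dx, (t + 0.5) dy)``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "LAND_USE_CHANNELS",
    "ACCIDENT_CHANNELS",
    "ISOLATION_LEVELS",
    "CROSS_SECTION_LEVELS",
    "GridSpec",
    "LandUseGrid",
    "AccidentGrid",
    "WindowSet",
    "VocabularyError",
    "encode_date",
    "encode_time",
    "encode_isolation",
    "encode_cross_section",
    "accident_count",
    "aggregate_characteristics",
    "minmax_scale",
    "inverse_minmax",
    "sample_windows",
    "split_train_test",
    "prepare_dataset",
]

#: Input channels: local land-use properties of a cell (fixed order).
LAND_USE_CHANNELS = (
    "plot_ratio",
    "poi_types",
    "centrality",
    "dist_cbd",
    "road_sections",
    "congestion_ratio",
)

#: Output channels: accident characteristics of a cell (fixed order).
ACCIDENT_CHANNELS = (
    "count",
    "date_to_winter",
    "time_to_1500",
    "isolation",
    "cross_section",
)

#: Ordinal encoding of road-isolation quality, best-separated first.
ISOLATION_LEVELS = {
    "Center isolation and motor vehicle-non-motor vehicle isolation": 4,
    "Center isolation": 3,
    "Motor vehicle and non-motor vehicle isolation": 2,
    "None": 1,
}

#: Ordinal encoding of the cross-sectional location of an accident.
CROSS_SECTION_LEVELS = {
    "Motor vehicle lane": 5,
    "Motor vehicle and non-motor vehicle mixed lane": 4,
    "Non-motor vehicle lane": 3,
    "sidewalk": 2,
    "cross walk": 1,
}

#: 15:00 expressed as seconds of day: the reference clock time.
PEAK_SECOND = 15 * 3600

SECONDS_PER_DAY = 86400


class VocabularyError(ValueError):
    """An accident label outside the closed label vocabulary."""


# ---------------------------------------------------------------------------
# Grid containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: size, planar origin and cell edge lengths (m)."""

    rows: int
    cols: int
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: tuple[float, float] = (400.0, 444.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size[0] <= 0 or self.cell_size[1] <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_centers(self) -> np.ndarray:
        """Planar coordinates of all cell centres, shape (rows, cols, 2)."""
        dx, dy = self.cell_size
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.cols) + 0.5) * dx
        ys = y0 + (np.arange(self.rows) + 0.5) * dy
        cx, cy = np.meshgrid(xs, ys)
        return np.stack([cx, cy], axis=-1)


@dataclass
class _ChannelGrid:
    spec: GridSpec
    values: np.ndarray  # (rows, cols, n_channels) float64
    mask: np.ndarray    # (rows, cols) bool, True where observed
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = (self.spec.rows, self.spec.cols, len(self.channels))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != {expected} from spec/channels"
            )
        if self.mask.shape != expected[:2]:
            raise ValueError("mask shape must be (rows, cols)")

    def channel(self, name: str) -> np.ndarray:
        """The (rows, cols) raster of a named channel."""
        return self.values[:, :, self.channels.index(name)]


@dataclass
class LandUseGrid(_ChannelGrid):
    """Six-channel raster of local land-use properties (the model input x)."""

    channels: tuple[str, ...] = LAND_USE_CHANNELS


@dataclass
class AccidentGrid(_ChannelGrid):
    """Five-channel raster of accident characteristics (the model target h).

    ``mask`` is False on cells with no accident within the aggregation
    radius: their characteristic values are undefined and excluded from any
    loss or statistic.
    """

    channels: tuple[str, ...] = ACCIDENT_CHANNELS


# ---------------------------------------------------------------------------
# Indicator encodings
# ---------------------------------------------------------------------------

def encode_date(d: dt.date) -> int:
    """Day distance from ``d`` to the nearest winter solstice (22 December).

    The solstice of the same year, the previous year and the next year are
    all candidates, so the value lies in [0, 183] on real calendars
    (183 is attained mid-summer in years adjoining a leap February).
    """
    if isinstance(d, dt.datetime):
        d = d.date()
    candidates = (
        dt.date(d.year - 1, 12, 22),
        dt.date(d.year, 12, 22),
        dt.date(d.year + 1, 12, 22),
    )
    return min(abs((d - c).days) for c in candidates)


def encode_time(t: float) -> float:
    """Same-day absolute second distance from ``t`` (seconds of day) to 15:00."""
    if not 0 <= t < SECONDS_PER_DAY:
        raise ValueError(f"time of day must lie in [0, 86400), got {t}")
    return abs(t - PEAK_SECOND)


def encode_isolation(label: str) -> int:
    """Ordinal level (1-4) of a road-isolation label."""
    try:
        return ISOLATION_LEVELS[label]
    except KeyError:
        raise VocabularyError(f"unknown isolation label: {label!r}") from None


def encode_cross_section(label: str) -> int:
    """Ordinal level (1-5) of a cross-sectional location label."""
    try:
        return CROSS_SECTION_LEVELS[label]
    except KeyError:
        raise VocabularyError(f"unknown cross-section label: {label!r}") from None


def encode_events(events: pd.DataFrame) -> pd.DataFrame:
    """Encode an event table's date/time/label columns to numeric indicators.

    Expects columns x, y, date (ISO string or date), time (seconds of day),
    isolation, cross_section; returns x, y plus the four encoded columns.
    """
    dates = pd.to_datetime(events["date"]).dt.date
    return pd.DataFrame(
        {
            "x": np.asarray(events["x"], dtype=float),
            "y": np.asarray(events["y"], dtype=float),
            "date_to_winter": [encode_date(d) for d in dates],
            "time_to_1500": [encode_time(t) for t in events["time"]],
            "isolation": [encode_isolation(l) for l in events["isolation"]],
            "cross_section": [encode_cross_section(l) for l in events["cross_section"]],
        }
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _events_xy(events: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [np.asarray(events["x"], dtype=float), np.asarray(events["y"], dtype=float)]
    )


def _neighbors_within(spec: GridSpec, xy: np.ndarray, radius: float) -> list[list[int]]:
    """For each cell (row-major), the indices of events within ``radius`` m."""
    centers = spec.cell_centers().reshape(-1, 2)
    if len(xy) == 0:
        return [[] for _ in range(len(centers))]
    tree = cKDTree(xy)
    return tree.query_ball_point(centers, r=radius)


def accident_count(spec: GridSpec, events: pd.DataFrame, radius: float = 3000.0) -> np.ndarray:
    """Number of events within ``radius`` metres of each cell centre.

    Returns an integer raster of shape (rows, cols).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    hits = _neighbors_within(spec, _events_xy(events), radius)
    counts = np.fromiter((len(h) for h in hits), dtype=int, count=spec.n_cells)
    return counts.reshape(spec.rows, spec.cols)


def aggregate_characteristics(
    spec: GridSpec, events: pd.DataFrame, radius: float = 3000.0
) -> AccidentGrid:
    """Aggregate encoded events to a five-channel accident raster.

    Per cell: the event count within ``radius`` of the cell centre, and the
    unweighted mean of each encoded characteristic over those events. Cells
    with no event in radius are masked as missing.

    ``events`` may be raw (date/time/label columns) or already encoded.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if "date_to_winter" not in events.columns:
        events = encode_events(events)
    hits = _neighbors_within(spec, _events_xy(events), radius)

    char_cols = ["date_to_winter", "time_to_1500", "isolation", "cross_section"]
    ev = events[char_cols].to_numpy(dtype=float)
    values = np.zeros((spec.n_cells, len(ACCIDENT_CHANNELS)))
    mask = np.zeros(spec.n_cells, dtype=bool)
    for g, idx in enumerate(hits):
        values[g, 0] = len(idx)
        if idx:
            values[g, 1:] = ev[idx].mean(axis=0)
            mask[g] = True
    return AccidentGrid(
        spec=spec,
        values=values.reshape(spec.rows, spec.cols, -1),
        mask=mask.reshape(spec.rows, spec.cols),
    )


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

class DegenerateScaleError(ValueError):
    """A channel is constant over the cells used to fit the scaling."""


ScalingParams = dict[str, tuple[float, float]]


def fit_scaling(grid: _ChannelGrid, cells: np.ndarray | None = None) -> ScalingParams:
    """Per-channel (min, max) over observed cells (optionally restricted)."""
    use = grid.mask if cells is None else (grid.mask & cells)
    if not use.any():
        raise ValueError("no observed cells to fit scaling on")
    params: ScalingParams = {}
    for k, name in enumerate(grid.channels):
        v = grid.values[:, :, k][use]
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            raise DegenerateScaleError(f"channel {name!r} is constant ({lo})")
        params[name] = (lo, hi)
    return params


def minmax_scale(
    grid: _ChannelGrid, params: ScalingParams | None = None
) -> tuple[_ChannelGrid, ScalingParams]:
    """Affinely map each channel to [0, 1]; returns the scaled grid and the
    (min, max) pairs needed to invert the map.

    If ``params`` is given it is applied as-is (values outside the fitted
    range then fall outside [0, 1]); otherwise the map is fitted on the
    grid's observed cells. Unobserved cells are scaled too (their values are
    placeholders guarded by the mask).
    """
    if params is None:
        params = fit_scaling(grid)
    scaled = grid.values.copy()
    for k, name in enumerate(grid.channels):
        lo, hi = params[name]
        scaled[:, :, k] = (grid.values[:, :, k] - lo) / (hi - lo)
    return dataclasses.replace(grid, values=scaled), params


def inverse_minmax(grid: _ChannelGrid, params: ScalingParams) -> _ChannelGrid:
    """Invert :func:`minmax_scale` (exact up to floating-point rounding)."""
    raw = grid.values.copy()
    for k, name in enumerate(grid.channels):
        lo, hi = params[name]
        raw[:, :, k] = grid.values[:, :, k] * (hi - lo) + lo
    return dataclasses.replace(grid, values=raw)


# ---------------------------------------------------------------------------
# Window sampling and splitting
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Overlapping square windows cut from an aligned land-use/accident pair.

    Arrays are indexed by window; ``split`` holds "train"/"test" for usable
    windows and "" for unusable ones. ``scaling_params`` records the
    per-channel (min, max) applied to inputs/targets (None if unscaled).
    """

    inputs: np.ndarray   # (N, size, size, 6)
    targets: np.ndarray  # (N, size, size, 5)
    masks: np.ndarray    # (N, size, size) bool, True where observed
    anchors: np.ndarray  # (N, 2) top-left (t, s) of each window
    usable: np.ndarray   # (N,) bool
    size: int = 9
    stride: int = 1
    split: np.ndarray | None = None
    scaling_params: dict[str, ScalingParams] | None = None

    def __post_init__(self) -> None:
        if self.split is None:
            self.split = np.full(len(self.usable), "", dtype=object)

    def __len__(self) -> int:
        return len(self.usable)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def subset(self, which: str) -> "WindowSet":
        """The train or test windows as a new WindowSet."""
        sel = self.split == which
        return WindowSet(
            inputs=self.inputs[sel],
            targets=self.targets[sel],
            masks=self.masks[sel],
            anchors=self.anchors[sel],
            usable=self.usable[sel],
            size=self.size,
            stride=self.stride,
            split=self.split[sel],
            scaling_params=self.scaling_params,
        )


def _sliding(arr: np.ndarray, size: int, stride: int) -> np.ndarray:
    """All size x size windows at the given stride, leading window axis."""
    from numpy.lib.stride_tricks import sliding_window_view

    if arr.ndim == 2:
        v = sliding_window_view(arr, (size, size))
    else:
        v = sliding_window_view(arr, (size, size), axis=(0, 1))
    v = v[::stride, ::stride]
    if arr.ndim == 2:
        return v.reshape(-1, size, size)
    # sliding_window_view leaves the channel axis in the middle
    return v.transpose(0, 1, 3, 4, 2).reshape(-1, size, size, arr.shape[2])


def sample_windows(
    landuse: LandUseGrid,
    accidents: AccidentGrid,
    size: int = 9,
    stride: int = 1,
    zero_rate_threshold: float = 0.8,
) -> WindowSet:
    """Cut all size x size windows and flag the usable ones.

    A cell is *missing* when either grid is unobserved there. A window is
    unusable when its missing fraction (the "zero rate") reaches
    ``zero_rate_threshold`` — at the default 0.8, windows with at least 80%
    missing cells are dropped. Missing cells that survive inside usable
    windows keep value 0 in the inputs and are excluded from losses via the
    window mask.
    """
    if landuse.spec.rows != accidents.spec.rows or landuse.spec.cols != accidents.spec.cols:
        raise ValueError("land-use and accident grids are not aligned")
    if size > min(landuse.spec.rows, landuse.spec.cols):
        raise ValueError(
            f"grid {landuse.spec.rows}x{landuse.spec.cols} is smaller than a "
            f"{size}x{size} window"
        )
    observed = landuse.mask & accidents.mask
    x = np.where(observed[:, :, None], landuse.values, 0.0)
    y = np.where(observed[:, :, None], accidents.values, 0.0)

    inputs = _sliding(x, size, stride)
    targets = _sliding(y, size, stride)
    masks = _sliding(observed, size, stride)

    n_t = (landuse.spec.rows - size) // stride + 1
    n_s = (landuse.spec.cols - size) // stride + 1
    tt, ss = np.meshgrid(np.arange(n_t) * stride, np.arange(n_s) * stride, indexing="ij")
    anchors = np.column_stack([tt.ravel(), ss.ravel()])

    missing_frac = 1.0 - masks.reshape(len(masks), -1).mean(axis=1)
    usable = missing_frac < zero_rate_threshold
    return WindowSet(
        inputs=inputs.copy(),
        targets=targets.copy(),
        masks=masks.copy(),
        anchors=anchors,
        usable=usable,
        size=size,
        stride=stride,
    )


def split_train_test(ws: WindowSet, n_test: int = 100, seed: int = 0) -> WindowSet:
    """Assign usable windows to train/test: ``n_test`` drawn uniformly
    without replacement, the rest train. Deterministic given ``seed``."""
    usable_idx = np.flatnonzero(ws.usable)
    if len(usable_idx) < n_test:
        raise ValueError(f"only {len(usable_idx)} usable windows, need {n_test} for test")
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(usable_idx, size=n_test, replace=False)
    split = np.full(len(ws), "", dtype=object)
    split[usable_idx] = "train"
    split[test_idx] = "test"
    return dataclasses.replace(ws, split=split)


def prepare_dataset(
    landuse: LandUseGrid,
    accidents: AccidentGrid,
    size: int = 9,
    stride: int = 1,
    zero_rate_threshold: float = 0.8,
    n_test: int = 100,
    seed: int = 0,
) -> WindowSet:
    """Full window pipeline: sample, split, then min-max scale to [0, 1].

    The scaling statistics are fitted only on observed cells covered by at
    least one *training* window, then applied to every window, so the held
    out windows leak nothing into the preprocessing.
    """
    ws = sample_windows(landuse, accidents, size, stride, zero_rate_threshold)
    ws = split_train_test(ws, n_test=n_test, seed=seed)

    covered = np.zeros((landuse.spec.rows, landuse.spec.cols), dtype=bool)
    for t, s in ws.anchors[ws.split == "train"]:
        covered[t : t + size, s : s + size] = True
    x_params = fit_scaling(landuse, covered)
    y_params = fit_scaling(accidents, covered)

    def scale(arr: np.ndarray, channels: tuple[str, ...], params: ScalingParams) -> np.ndarray:
        out = arr.copy()
        for k, name in enumerate(channels):
            lo, hi = params[name]
            out[:, :, :, k] = (arr[:, :, :, k] - lo) / (hi - lo)
        return out

    inputs = scale(ws.inputs, LAND_USE_CHANNELS, x_params)
    targets = scale(ws.targets, ACCIDENT_CHANNELS, y_params)
    # re-impute missing cells to 0 on the scaled scale
    inputs[~ws.masks] = 0.0
    targets[~ws.masks] = 0.0
    return dataclasses.replace(
        ws,
        inputs=inputs,
        targets=targets,
        scaling_params={"landuse": x_params, "accidents": y_params},
    )
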