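"""Synthetic city generator: land-use rasters, accident events, teacher grids.

No study data are deposited for the original Shenyang analysis, so this
module fabricates inputs with the same structure, ranges and spatial
character, giving every downstream stage a testable ground truth:

* land-use channels are smoothed Gaussian random fields (white noise
  convolved with a Gaussian kernel of width ``correlation_length``) rescaled
  affinely to the configured per-channel ranges — smoothing guarantees the
  positive spatial autocorrelation the real rasters exhibit;
* accident events are a spatial point process whose intensity increases
  with land-use activity, with winter-peaked dates (point mass at the
  22 December solstice mixed with a uniform background — a deliberately
  crude stand-in for the seasonal peak), afternoon-peaked times
  (13:00-17:00 block mixed with a uniform background), and categorical
  road-layout labels;
* teacher targets run a known grid-recurrence parameter set forward over
  the land-use raster (plus Gaussian noise, clipped to [0, 1]) so that
  training can be validated by parameter/function recovery.

All generators are pure functions of (config, seed); per-channel and
per-operation substreams are derived from the master seed so adding a
channel never perturbs the others.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import model as _model
from .raster import (
    ACCIDENT_CHANNELS,
    CROSS_SECTION_LEVELS,
    ISOLATION_LEVELS,
    LAND_USE_CHANNELS,
    AccidentGrid,
    GridSpec,
    LandUseGrid,
)

__all__ = [
    "SyntheticConfig",
    "AccidentEvent",
    "DEFAULT_CHANNEL_RANGES",
    "gen_landuse",
    "gen_accident_events",
    "gen_accidents_from_teacher",
    "teacher_windows",
    "events_to_frame",
]

#: Per-channel (min, max) targets, matching the published overview of the
#: real land-use attributes (plot ratio 0-6.62, 2-13 POI types, centrality
#: and CBD distance in metres, 0-221 surrounding road sections, congestion
#: ratio 0-0.486).
DEFAULT_CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "plot_ratio": (0.0, 6.62),
    "poi_types": (2.0, 13.0),
    "centrality": (4.49e3, 3.37e4),
    "dist_cbd": (643.0, 3.21e4),
    "road_sections": (0.0, 221.0),
    "congestion_ratio": (0.0, 0.486),
}

#: Marginal label frequencies: mostly unseparated roads, accidents mostly in
#: motor-vehicle lanes (chosen once as plausible urban frequencies).
DEFAULT_ISOLATION_PROBS = {
    "Center isolation and motor vehicle-non-motor vehicle isolation": 0.05,
    "Center isolation": 0.10,
    "Motor vehicle and non-motor vehicle isolation": 0.15,
    "None": 0.70,
}
DEFAULT_CROSS_SECTION_PROBS = {
    "Motor vehicle lane": 0.75,
    "Motor vehicle and non-motor vehicle mixed lane": 0.15,
    "Non-motor vehicle lane": 0.05,
    "sidewalk": 0.03,
    "cross walk": 0.02,
}

_STUDY_START = dt.date(2015, 1, 1)
_STUDY_END = dt.date(2017, 12, 31)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    rows/cols default to the source study's raster (~96 x 125 cells of
    400 m x 444 m); correlation_length (metres) sets the Gaussian kernel
    width of the land-use fields; winter_peak_weight is the fraction of
    events dated exactly on the winter solstice; afternoon_peak_weight the
    fraction timed uniformly within 13:00-17:00.
    """

    rows: int = 96
    cols: int = 125
    cell_size: tuple[float, float] = (400.0, 444.0)
    correlation_length: float = 2000.0
    channel_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_RANGES)
    )
    winter_peak_weight: float = 0.6
    afternoon_peak_weight: float = 0.55
    isolation_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOLATION_PROBS)
    )
    cross_section_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CROSS_SECTION_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 9 or self.cols < 9:
            raise ValueError("grid must be at least 9 x 9 (one window must fit)")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        for name, (lo, hi) in self.channel_ranges.items():
            if not lo < hi:
                raise ValueError(f"channel range for {name!r} must have min < max")
        if not 0.0 <= self.winter_peak_weight <= 1.0:
            raise ValueError("winter_peak_weight must lie in [0, 1]")
        for lbl in self.isolation_probs:
            if lbl not in ISOLATION_LEVELS:
                raise ValueError(f"unknown isolation label {lbl!r}")
        for lbl in self.cross_section_probs:
            if lbl not in CROSS_SECTION_LEVELS:
                raise ValueError(f"unknown cross-section label {lbl!r}")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(rows=self.rows, cols=self.cols, cell_size=self.cell_size)


@dataclass(frozen=True)
class AccidentEvent:
    """One injury accident: planar location, calendar date, seconds-of-day
    time, and the two road-layout labels."""

    x: float
    y: float
    date: dt.date
    time: int
    isolation: str
    cross_section: str

    def __post_init__(self) -> None:
        if not 0 <= self.time < 86400:
            raise ValueError("time must lie in [0, 86400)")
        if self.isolation not in ISOLATION_LEVELS:
            raise ValueError(f"unknown isolation label {self.isolation!r}")
        if self.cross_section not in CROSS_SECTION_LEVELS:
            raise ValueError(f"unknown cross-section label {self.cross_section!r}")


def _rng(config: SyntheticConfig, *key: int) -> np.random.Generator:
    """Substream generator: master seed + an integer key path."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def gen_landuse(config: SyntheticConfig) -> LandUseGrid:
    """Six smoothed-random-field channels, each rescaled exactly to its
    configured (min, max). Deterministic given the config seed."""
    sigma_cells = (
        config.correlation_length / config.cell_size[1],
        config.correlation_length / config.cell_size[0],
    )
    values = np.zeros((config.rows, config.cols, len(LAND_USE_CHANNELS)))
    for k, name in enumerate(LAND_USE_CHANNELS):
        rng = _rng(config, 0, k)
        noise = rng.standard_normal((config.rows, config.cols))
        smooth = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
        lo, hi = config.channel_ranges[name]
        smin, smax = smooth.min(), smooth.max()
        values[:, :, k] = lo + (smooth - smin) / (smax - smin) * (hi - lo)
    mask = np.ones((config.rows, config.cols), dtype=bool)
    return LandUseGrid(spec=config.spec, values=values, mask=mask)


def _sample_dates(rng: np.random.Generator, n: int, w: float) -> list[dt.date]:
    n_days = (_STUDY_END - _STUDY_START).days + 1
    winter = rng.random(n) < w
    offsets = rng.integers(0, n_days, size=n)
    solstices = [dt.date(y, 12, 22) for y in (2015, 2016, 2017)]
    pick = rng.integers(0, len(solstices), size=n)
    return [
        solstices[pick[j]] if winter[j] else _STUDY_START + dt.timedelta(days=int(offsets[j]))
        for j in range(n)
    ]


def _sample_times(rng: np.random.Generator, n: int, w: float) -> np.ndarray:
    peak = rng.random(n) < w
    t_peak = rng.integers(13 * 3600, 17 * 3600, size=n)
    t_unif = rng.integers(0, 86400, size=n)
    return np.where(peak, t_peak, t_unif)


def gen_accident_events(
    landuse: LandUseGrid, config: SyntheticConfig, n_events: int
) -> list[AccidentEvent]:
    """Sample ``n_events`` accident points over the land-use raster.

    Cell intensity is exp of the average standardized land-use channel
    (activity-dense cells attract more events); locations are uniform within
    the chosen cell. Dates, times and labels follow the configured mixtures.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    spec = landuse.spec
    z = (landuse.values - landuse.values.mean(axis=(0, 1))) / (
        landuse.values.std(axis=(0, 1)) + 1e-12
    )
    intensity = np.exp(0.5 * z.mean(axis=2)).ravel()
    prob = intensity / intensity.sum()

    rng = _rng(config, 1)
    cells = rng.choice(spec.n_cells, size=n_events, p=prob)
    tt, ss = np.divmod(cells, spec.cols)
    dx, dy = spec.cell_size
    x0, y0 = spec.origin
    xs = x0 + (ss + rng.random(n_events)) * dx
    ys = y0 + (tt + rng.random(n_events)) * dy

    dates = _sample_dates(rng, n_events, config.winter_peak_weight)
    times = _sample_times(rng, n_events, config.afternoon_peak_weight)
    iso_labels = list(config.isolation_probs)
    iso_p = np.array([config.isolation_probs[l] for l in iso_labels], dtype=float)
    iso = rng.choice(len(iso_labels), size=n_events, p=iso_p / iso_p.sum())
    cs_labels = list(config.cross_section_probs)
    cs_p = np.array([config.cross_section_probs[l] for l in cs_labels], dtype=float)
    cs = rng.choice(len(cs_labels), size=n_events, p=cs_p / cs_p.sum())

    return [
        AccidentEvent(
            x=float(xs[j]),
            y=float(ys[j]),
            date=dates[j],
            time=int(times[j]),
            isolation=iso_labels[iso[j]],
            cross_section=cs_labels[cs[j]],
        )
        for j in range(n_events)
    ]


def events_to_frame(events: list[AccidentEvent]) -> pd.DataFrame:
    """Event list as the canonical CSV table (dates ISO-8601)."""
    return pd.DataFrame(
        {
            "x": [e.x for e in events],
            "y": [e.y for e in events],
            "date": [e.date.isoformat() for e in events],
            "time": [e.time for e in events],
            "isolation": [e.isolation for e in events],
            "cross_section": [e.cross_section for e in events],
        }
    )


def _scaled_input(landuse: LandUseGrid) -> np.ndarray:
    """Min-max scale the land-use channels to [0, 1] (the model's input scale)."""
    v = landuse.values
    lo = v.min(axis=(0, 1))
    hi = v.max(axis=(0, 1))
    return (v - lo) / np.where(hi > lo, hi - lo, 1.0)


def random_teacher(
    seed: int = 0,
    scale: float = 0.5,
    forget_bias: float = -1.0,
    state_bias: float = 0.5,
    coupled: bool = False,
) -> "_model.MDLSTMParams":
    """A random ground-truth parameter set for recovery experiments.

    Weights are uniform in +-scale. The candidate-state bias is positive so
    the teacher's outputs mostly occupy the positive part of (-1, 1) — the
    region the [0, 1]-scaled targets live in. Forget biases default to -1
    (gate ~0.27 per direction, keeping the state recursion contractive);
    ``coupled=True`` sets them to +1 instead, making neighbour transfer the
    dominant term (strong spatial coupling).
    """
    p = _model.MDLSTMParams.random(
        seed=seed, scale=scale, forget_bias=(1.0 if coupled else forget_bias)
    )
    p.b_C += state_bias
    return p


def gen_accidents_from_teacher(
    landuse: LandUseGrid,
    teacher: "_model.MDLSTMParams",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AccidentGrid:
    """Run a known ("teacher") parameter set forward over the scaled
    land-use grid, add i.i.d. Gaussian noise, clip to [0, 1]; every cell is
    observed. Used for parameter/function-recovery experiments."""
    if teacher.d_x != len(landuse.channels):
        raise ValueError(
            f"teacher expects {teacher.d_x} input channels, grid has {len(landuse.channels)}"
        )
    if teacher.d_h != len(ACCIDENT_CHANNELS):
        raise ValueError("teacher hidden width must match the accident channels")
    x = _scaled_input(landuse)
    h = _model.grid_forward(x, teacher).h
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        h = h + rng.normal(0.0, noise_sd, size=h.shape)
    if noise_sd > 0:
        h = np.clip(h, 0.0, 1.0)
    mask = np.ones((landuse.spec.rows, landuse.spec.cols), dtype=bool)
    return AccidentGrid(spec=landuse.spec, values=h, mask=mask)


def teacher_windows(
    landuse: LandUseGrid,
    teacher: "_model.MDLSTMParams",
    noise_sd: float = 0.0,
    seed: int = 0,
    size: int = 9,
    n_windows: int | None = None,
    n_test: int = 100,
) -> "object":
    """Window-level teacher data: cut all size x size input windows from the
    scaled land-use grid, run the teacher on each window independently (zero
    boundary, exactly the conditions a student sees), add noise, and split.

    Returns a :class:`~gridrisk.raster.WindowSet` ready for training.
    """
    from . import raster as _raster

    x = _scaled_input(landuse)
    from numpy.lib.stride_tricks import sliding_window_view

    wins = sliding_window_view(x, (size, size), axis=(0, 1))
    wins = wins.transpose(0, 1, 3, 4, 2).reshape(-1, size, size, x.shape[2]).copy()
    if n_windows is not None:
        if n_windows > len(wins):
            raise ValueError(f"grid yields only {len(wins)} windows")
        wins = wins[:n_windows]
    f, _ = _model._forward_batch(wins, teacher)
    targets = f.h
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        targets = np.clip(targets + rng.normal(0.0, noise_sd, size=targets.shape), 0.0, 1.0)
    ws = _raster.WindowSet(
        inputs=wins,
        targets=targets,
        masks=np.ones(wins.shape[:3], dtype=bool),
        anchors=np.zeros((len(wins), 2), dtype=int),
        usable=np.ones(len(wins), dtype=bool),
        size=size,
    )
    return _raster.split_train_test(ws, n_test=n_test, seed=seed)
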