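import numpy as np
import pytest

import gridrisk as g
from gridrisk import synthetic as syn


@pytest.fixture(scope="session")
def small_city():
    """A 20x20 synthetic city: land-use grid plus 600 accident events."""
    cfg = g.SyntheticConfig(rows=20, cols=20, seed=42)
    landuse = syn.gen_landuse(cfg)
    events = syn.gen_accident_events(landuse, cfg, 600)
    return cfg, landuse, syn.events_to_frame(events)


@pytest.fixture(scope="session")
def small_field():
    """Forward state field of a random model on a random 9x9 window."""
    rng = np.random.default_rng(7)
    p = g.MDLSTMParams.random(seed=7)
    X = rng.random((9, 9, 6))
    return p, X, g.grid_forward(X, p)


def random_window(seed, rows=9, cols=9):
    rng = np.random.default_rng(seed)
    return rng.random((rows, cols, 6)), rng.random((rows, cols, 5))
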