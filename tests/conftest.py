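import numpy as np
import pytest

from relaymea import SimulationConfig, two_slice_grid
from relaymea.recording import EventRaster


@pytest.fixture(scope="session")
def layout():
    return two_slice_grid()


@pytest.fixture(scope="session")
def small_layout():
    return two_slice_grid(n_per_slice=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raster(layout, events, duration=10.0):
    """Helper: raster from a list of (electrode_id, time) pairs."""
    if events:
        ids, times = zip(*events)
    else:
        ids, times = (), ()
    return EventRaster(
        electrode_ids=np.asarray(ids, dtype=np.int64),
        times=np.asarray(times, dtype=float),
        duration=duration,
        layout=layout,
    )


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(duration_s=120.0, seed=7)
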