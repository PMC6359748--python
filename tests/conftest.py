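import numpy as np
import pytest

from mcchain.signals import RngHandle, TimeGrid, Trace


@pytest.fixture
def grid():
    return TimeGrid(0.0, 40.0, 0.001)


@pytest.fixture
def coarse_grid():
    return TimeGrid(0.0, 40.0, 0.01)


@pytest.fixture
def rng():
    return RngHandle(12345)


def make_trace(grid: TimeGrid, values, units="arbitrary") -> Trace:
    return Trace(grid, np.asarray(values, dtype=float), units=units)
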