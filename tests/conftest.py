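import numpy as np
import pytest

from cellpick import ArenaGeometry, CellRecord, FrameSpec, RenderParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arena():
    return ArenaGeometry.square(1000.0)


@pytest.fixture
def frame_spec():
    return FrameSpec(width=200, height=200, pixel_size=2.0)


@pytest.fixture
def noiseless():
    return RenderParams(noise_sd=0.0)


def cell(x, y, cid=0, size=16.0, brightness=500.0, labeled=True):
    return CellRecord(id=cid, x=x, y=y, size=size, brightness=brightness, labeled=labeled)
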