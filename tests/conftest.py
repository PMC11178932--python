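import numpy as np
import pytest
from hypothesis import settings

from archtrack import BBox

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def stepped_mask():
    """20x10 crop whose dorsal line steps 4 -> 2 -> 3 across thirds.

    Sample columns at 15/50/85% of width 20 are 3, 10, 17, so the three
    curvature points are (3,4), (10,2), (17,3).
    """
    mask = np.zeros((10, 20), dtype=bool)
    for c in range(20):
        top = 4 if c < 7 else (2 if c < 14 else 3)
        mask[top:, c] = True
    return mask


def solid(h, w):
    return np.ones((h, w), dtype=bool)


@pytest.fixture
def frame_with_stepped(stepped_mask):
    """The stepped crop embedded in an empty 20x40 frame at offset (0, 10)."""
    frame = np.zeros((20, 40), dtype=bool)
    frame[10:20, 0:20] = stepped_mask
    return frame, BBox(0, 10, 20, 20)
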