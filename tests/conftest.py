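import numpy as np
import pytest

from gazebehave.core import GazeRecording, ScreenGeometry


@pytest.fixture
def geometry():
    return ScreenGeometry(
        width_px=1920,
        height_px=1080,
        physical_width_mm=510.0,
        physical_height_mm=287.0,
        viewing_distance_mm=600.0,
    )


def make_recording(x, y, rate_hz=40.0, unit="degrees", geometry=None,
                   left=None, right=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) * 1000.0 / rate_hz
    return GazeRecording(
        t=t,
        x=x,
        y=np.asarray(y, dtype=float),
        left_valid=left,
        right_valid=right,
        geometry=geometry,
        unit=unit,
        nominal_rate=rate_hz,
    )


@pytest.fixture
def make_rec():
    return make_recording


def random_trace(rng, n=None, rate_hz=40.0):
    """Random short gaze trace mixing slow wander and occasional jumps."""
    n = n or int(rng.integers(5, 51))
    x = np.zeros(n)
    y = np.zeros(n)
    pos = rng.uniform(-5, 5, size=2)
    for i in range(n):
        if rng.uniform() < 0.15:
            pos = pos + rng.uniform(-8, 8, size=2)
        else:
            pos = pos + rng.normal(0, 0.15, size=2)
        x[i], y[i] = pos
    return make_recording(x, y, rate_hz=rate_hz)
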