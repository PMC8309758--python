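import numpy as np
import pytest

from accelalign import synthetic_data as sd
from accelalign.signal_io import TriaxialRecording


def make_recording(values, fs=30.0, **kwargs) -> TriaxialRecording:
    """Recording from an (n, 3) array or a z-axis 1-D array (gravity added)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        samples = np.zeros((len(values), 3))
        samples[:, 2] = values
    else:
        samples = values
    return TriaxialRecording(samples=samples, fs=fs, **kwargs)


@pytest.fixture(scope="session")
def eight_hour_pair():
    """8-hour pair with one staggered walk per hour, 200 ppm skew, 1 s offset.

    The large skew makes the lag-vs-time slope clearly measurable over a
    short recording (lag changes by ~170 samples across 8 h).
    """
    script = sd.ActivityScript(
        [sd.Segment(h * 3600 + 600 + 120 * h, 600, "walk", 0.4) for h in range(8)])
    clock = sd.ClockSpec(skew_ppm=200.0, offset_s=1.0)
    ref, sec, truth = sd.generate_pair(script, clock, days=8 / 24, seed=3)
    return ref, sec, truth
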