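import numpy as np
import pytest

from eggdenoise import SignalTrack

RATE = 44100.0


@pytest.fixture
def rate():
    return RATE


def make_sine(fo=220.0, peak_dbfs=-13.0, duration=1.0, rate=RATE, phase=0.0):
    n = int(round(duration * rate))
    amp = 10.0 ** (peak_dbfs / 20.0)
    return SignalTrack(
        amp * np.sin(2 * np.pi * fo * np.arange(n) / rate + phase), rate=rate
    )


@pytest.fixture
def sine_220():
    """1 s, 220 Hz sine at −13 dBFS: the workhorse test signal."""
    return make_sine()
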