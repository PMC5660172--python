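import numpy as np
import pytest

from tauconn.core_io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone_recording(freq_hz: float, fs: float = 500.0, duration: float = 60.0,
                   amp: float = 10.0, labels=("A",)) -> Recording:
    t = np.arange(int(round(duration * fs))) / fs
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    return Recording(np.tile(x, (len(labels), 1)), fs, labels)


def noise_recording(rng, fs: float = 500.0, duration: float = 60.0,
                    rms: float = 20.0, labels=("A",)) -> Recording:
    n = int(round(duration * fs))
    return Recording(rng.standard_normal((len(labels), n)) * rms, fs, labels)
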