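import numpy as np
import pytest

from ppgplus.waveform import Waveform

FS = 125.0


def tone(freq_hz: float, duration_s: float = 10.0, fs: float = FS, amp: float = 1.0,
         phase: float = 0.0) -> Waveform:
    t = np.arange(round(duration_s * fs)) / fs
    return Waveform(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
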