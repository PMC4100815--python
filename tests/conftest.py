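import numpy as np
import pytest

from vocalid import Waveform, spectrogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory for pure-tone waveforms."""

    def _make(freq_hz: float, rate: int = 22050, duration_s: float = 0.5) -> Waveform:
        t = np.arange(int(round(duration_s * rate))) / rate
        return Waveform(samples=0.8 * np.sin(2 * np.pi * freq_hz * t), rate=rate)

    return _make


@pytest.fixture
def tone_spectrogram(tone):
    def _make(freq_hz: float, rate: int = 22050, duration_s: float = 0.5):
        return spectrogram(tone(freq_hz, rate, duration_s))

    return _make
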