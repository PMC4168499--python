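import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from physiofuse import ChannelSeries, MultichannelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def series_factory():
    def make(samples, fs=4.0, name="HR"):
        return ChannelSeries(name=name, samples=np.asarray(samples, dtype=float), fs=fs)

    return make


@pytest.fixture
def sine_series(series_factory):
    def make(freq, fs=4.0, duration=256.0, amp=1.0, name="HR"):
        t = np.arange(int(duration * fs)) / fs
        return series_factory(amp * np.sin(2 * np.pi * freq * t), fs=fs, name=name)

    return make


@pytest.fixture
def recording_factory(series_factory):
    def make(columns: dict, fs=4.0, label=None):
        channels = [series_factory(v, fs=fs, name=k) for k, v in columns.items()]
        return MultichannelRecording(channels=channels, label=label)

    return make
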