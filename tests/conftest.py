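import numpy as np
import pytest

from pcghr.envelope import FilterBankSpec, build_filterbank
from pcghr.pipeline import run_pipeline
from pcghr.synth import SynthConfig, generate

FS_CONDITIONED = 220.5


@pytest.fixture(scope="session")
def bank():
    """Default 15-band Meyer filter bank at the conditioned rate."""
    return build_filterbank(FilterBankSpec(), FS_CONDITIONED)


@pytest.fixture(scope="session")
def clean_recording():
    """Two minutes of clean 70 bpm synthetic neck PCG with its truth."""
    return generate(SynthConfig(duration=120.0, hr_bpm=70.0, seed=11))


@pytest.fixture(scope="session")
def clean_result(clean_recording):
    rec, _ = clean_recording
    return run_pipeline(rec)


def tone(freq, duration=4.0, fs=FS_CONDITIONED, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)
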