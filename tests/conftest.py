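import numpy as np
import pytest

from breathvoice.core import MonoSignal, VoiceSample
from breathvoice.synthdata import SynthParams, breathiness_to_oq, gen_egg, gen_voice


@pytest.fixture(scope="session")
def fs16k() -> float:
    return 16000.0


@pytest.fixture(scope="session")
def make_voice():
    """Factory for a 2-s synthetic voice at a given breathiness level."""

    def _make(breathiness: float = 0.0, f0: float = 220.0, seed: int = 7,
              sample_rate: float = 16000.0, **kw) -> MonoSignal:
        params = SynthParams(f0_hz=f0, duration_s=2.0,
                             breathiness_level=breathiness,
                             oq_target=breathiness_to_oq(breathiness),
                             sample_rate=sample_rate, seed=seed, **kw)
        return gen_voice(params)

    return _make


@pytest.fixture(scope="session")
def make_pair():
    """Factory for a paired CM+EGG sample sharing one f0 and breathiness."""

    def _make(breathiness: float = 0.0, f0: float = 220.0, seed: int = 7,
              sample_rate: float = 16000.0) -> VoiceSample:
        params = SynthParams(f0_hz=f0, duration_s=2.0,
                             breathiness_level=breathiness,
                             oq_target=breathiness_to_oq(breathiness),
                             sample_rate=sample_rate, seed=seed)
        return VoiceSample(sample_id="000", cm=gen_voice(params),
                           egg=gen_egg(params))

    return _make


def sine(freq: float, duration: float, fs: float, amp: float = 0.5) -> MonoSignal:
    t = np.arange(int(duration * fs)) / fs
    return MonoSignal(amp * np.sin(2 * np.pi * freq * t), fs)
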