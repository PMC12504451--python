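import numpy as np
import pytest

from slecg.io import Signal
from slecg.synthetic import SynthConfig, synth_record


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def clean_beat_train():
    """Noiseless 10 s / 100 Hz normal sinus train plus its ground truth."""
    record, truth = synth_record(SynthConfig(seed=11, heart_rate_bpm=72))
    return record.signals[0], truth


def make_signal(samples, fs=100.0, lead="I") -> Signal:
    return Signal(np.asarray(samples, dtype=float), fs, lead=lead)
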