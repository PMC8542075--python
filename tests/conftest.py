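import numpy as np
import pytest

from tnrlab.audio import AudioSignal
from tnrlab.synth import gen_babble, gen_cafeteria, gen_click_train, gen_speech_track

FS = 16_000

#: deterministic click times used by the transient-suppression fixtures;
#: spaced so the gain fully recovers between events
CLICK_TIMES = np.arange(0.5, 4.6, 0.4)


@pytest.fixture(scope="session")
def babble_bed():
    """5 s speech-shaped babble at 80 dB SPL-eq."""
    return gen_babble(5.0, 80.0, seed=1)


@pytest.fixture(scope="session")
def click_mix(babble_bed):
    """Babble bed plus a train of 1 ms-onset clicks 20 dB above the bed."""
    clicks = gen_click_train(CLICK_TIMES, peak_spl=100.0, duration=5.0)
    return babble_bed.with_samples(babble_bed.samples + clicks.samples)


@pytest.fixture(scope="session")
def cafeteria():
    return gen_cafeteria(5.0, 80.0, seed=12)


@pytest.fixture(scope="session")
def speech_track():
    """Short concatenated-sentence track for characterization tests."""
    return gen_speech_track(n_sentences=4, seed=11)


@pytest.fixture()
def tone():
    def make(level_spl=70.0, freq=1000.0, dur=1.0, rate=FS, spl_ref=110.0):
        t = np.arange(int(dur * rate)) / rate
        amp = 10.0 ** ((level_spl - spl_ref) / 20.0) * np.sqrt(2.0)
        return AudioSignal(amp * np.sin(2 * np.pi * freq * t), rate=rate,
                           spl_ref=spl_ref)
    return make
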