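"""Synthetic-audio generators: calibration, determinism, event statistics."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from tnrlab.audio import AudioSignal
from tnrlab.metrics import THIRD_OCTAVE_CENTERS_HZ
from tnrlab.synth import (NoiseRecipe, SentenceTokens, gen_babble,
                          gen_cafeteria, gen_clatter, gen_sentence,
                          gen_speech_track, mix_at_snr, speech_shape)

FS = 16_000


class TestBabble:
    def test_rms_calibration(self):
        assert gen_babble(5.0, 80.0, seed=1).rms_spl == pytest.approx(80.0, abs=0.1)

    def test_level_linearity_same_seed(self):
        hi = gen_babble(5.0, 80.0, seed=1)
        lo = gen_babble(5.0, 60.0, seed=1)
        assert hi.rms_spl - lo.rms_spl == pytest.approx(20.0, abs=1e-9)
        ratio = hi.samples / lo.samples
        assert np.allclose(ratio, ratio[0])

    def test_seed_determinism(self):
        a = gen_babble(2.0, 80.0, seed=7)
        b = gen_babble(2.0, 80.0, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seeds_decorrelate(self):
        a = gen_babble(2.0, 80.0, seed=1).samples
        b = gen_babble(2.0, 80.0, seed=2).samples
        corr = scipy.signal.fftconvolve(a, b[::-1], mode="full")
        peak = np.max(np.abs(corr)) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert peak < 0.2

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_babble(0.0, 80.0, seed=1)

    def test_third_octave_spectrum_matches_template(self):
        """Long-term per-band levels follow the speech-shaped template
        within 3 dB (FFT-shaped synthesis, finite-sample wiggle only)."""
        x = gen_babble(5.0, 80.0, seed=3)
        f, pxx = scipy.signal.welch(x.samples, fs=FS, nperseg=8192)
        template = speech_shape(f) ** 2
        offsets = []
        for c in THIRD_OCTAVE_CENTERS_HZ:
            lo, hi = c / 2 ** (1 / 6), c * 2 ** (1 / 6)
            m = (f >= lo) & (f < min(hi, FS / 2))
            if not m.any() or c >= FS / 2:
                continue
            offsets.append(10 * np.log10(pxx[m].sum() / template[m].sum()))
        offsets = np.asarray(offsets)
        assert np.ptp(offsets) < 3.0


class TestClatter:
    def test_rise_time_bound(self):
        """10-90% rise of each event's envelope stays within onset_ms."""
        recipe = NoiseRecipe(duration=5.0, transient_rate=2.0, onset_ms=1.0,
                             seed=5)
        sig, onsets = gen_clatter(recipe, with_events=True)
        env = np.abs(scipy.signal.hilbert(sig.samples))
        n_rise = int(recipe.onset_ms * 1e-3 * FS)
        for t0 in onsets:
            i0 = int(round(t0 * FS))
            seg = env[i0: i0 + 2 * n_rise]
            ref = seg[n_rise]                  # envelope at nominal rise end
            t10 = np.argmax(seg >= 0.1 * ref)
            t90 = np.argmax(seg >= 0.9 * ref)
            assert (t90 - t10) / FS <= 1.1e-3

    def test_event_count_poisson_interval(self):
        """Detected peak count (independent threshold-crossing oracle) lies
        in the Poisson 99% interval of mean rate*duration = 10."""
        recipe = NoiseRecipe(duration=5.0, transient_rate=2.0, seed=7)
        sig, onsets = gen_clatter(recipe, with_events=True)
        # oracle: count excursions of the rectified signal above half the
        # typical event peak, merged within 30 ms (can only merge true
        # events, never invent extra ones)
        thr = 0.5 * 10 ** ((recipe.level_spl + recipe.peak_excess_db
                            - sig.spl_ref) / 20)
        above = np.flatnonzero(np.abs(sig.samples) > thr)
        count = 0 if above.size == 0 else 1 + int(
            np.sum(np.diff(above) > 0.03 * FS))
        assert 2 <= count <= 21          # Poisson(10) 99% interval
        assert 2 <= len(onsets) <= 21
        assert count <= len(onsets)

    def test_event_span_within_one_second(self):
        recipe = NoiseRecipe(duration=3.0, transient_rate=1.0, seed=3)
        assert recipe.onset_ms + 8 * recipe.decay_ms_range[1] <= 1000.0

    def test_zero_rate_is_silent(self):
        sig = gen_clatter(NoiseRecipe(duration=2.0, transient_rate=0.0, seed=1))
        assert np.all(sig.samples == 0.0)

    def test_invalid_onset_rejected(self):
        with pytest.raises(ValueError):
            NoiseRecipe(onset_ms=0.0)
        with pytest.raises(ValueError):
            NoiseRecipe(onset_ms=2000.0)


class TestCafeteria:
    def test_rms_calibration(self):
        assert gen_cafeteria(5.0, 80.0, seed=3).rms_spl == pytest.approx(80.0,
                                                                         abs=0.1)

    def test_loop_preserves_level(self):
        x = gen_cafeteria(5.0, 80.0, seed=3)
        assert x.loop_to(40.0).rms_spl == pytest.approx(x.rms_spl, abs=0.1)

    def test_loop_has_no_endpoint_click(self):
        """Jump across the loop seam is comparable to ordinary
        sample-to-sample jumps (periodic FFT synthesis)."""
        x = gen_cafeteria(5.0, 80.0, seed=3)
        seam = abs(x.samples[0] - x.samples[-1])
        typical = np.percentile(np.abs(np.diff(x.samples)), 99)
        assert seam < 3 * typical

    def test_seed_determinism(self):
        a = gen_cafeteria(2.0, 80.0, seed=9)
        b = gen_cafeteria(2.0, 80.0, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestSentence:
    def test_five_words_with_increasing_onsets(self):
        sig, tokens = gen_sentence(77.0, seed=5)
        assert len(tokens.words) == 5
        assert all(b > a for a, b in zip(tokens.onsets, tokens.onsets[1:]))
        assert sig.rms_spl == pytest.approx(77.0, abs=0.2)

    def test_level_is_pure_gain(self):
        a, _ = gen_sentence(77.0, seed=5)
        b, _ = gen_sentence(74.0, seed=5)
        assert a.rms_spl - b.rms_spl == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(a.samples, b.samples * 10 ** (3 / 20))

    def test_bad_token_shapes_rejected(self):
        with pytest.raises(ValueError):
            SentenceTokens(("a", "b"), (0.0, 0.1))
        with pytest.raises(ValueError):
            SentenceTokens(("a",) * 5, (0.0, 0.2, 0.1, 0.3, 0.4))

    def test_twenty_sentences_make_characterization_track(self):
        track = gen_speech_track(n_sentences=20, seed=2)
        assert 30.0 < track.duration < 50.0
        assert track.rms_spl == pytest.approx(77.0, abs=0.2)


class TestMixAtSnr:
    def test_snr_and_lead(self, cafeteria):
        sp, _ = gen_sentence(77.0, seed=5)
        mix = mix_at_snr(sp, cafeteria, -2.0, lead_s=1.5)
        n_lead = int(1.5 * FS)
        # the lead is noise-only: identical to the looped noise track
        np.testing.assert_array_equal(
            mix.samples[:n_lead],
            cafeteria.loop_to(mix.duration).samples[:n_lead])
        overlap = mix.samples[n_lead:]
        noise_part = cafeteria.loop_to(mix.duration).samples[n_lead:len(mix)]
        speech_part = overlap - noise_part
        snr = 20 * np.log10(np.std(speech_part) / np.std(noise_part))
        assert snr == pytest.approx(-2.0, abs=0.1)

    def test_rate_mismatch_rejected(self, cafeteria):
        sp = AudioSignal(np.ones(100), rate=8000)
        with pytest.raises(ValueError):
            mix_at_snr(sp, cafeteria, 0.0)

    def test_infinite_snr_is_padded_speech(self, cafeteria):
        sp, _ = gen_sentence(77.0, seed=5)
        mix = mix_at_snr(sp, cafeteria, np.inf, lead_s=1.5)
        n_lead = int(1.5 * FS)
        assert np.all(mix.samples[:n_lead] == 0.0)
        assert np.array_equal(mix.samples[n_lead:], sp.samples)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(level=st.floats(min_value=50.0, max_value=90.0),
       delta=st.floats(min_value=-10.0, max_value=10.0))
def test_level_calibration_is_linear(level, delta):
    """Requesting level L + k yields exactly k dB more rms, same seed."""
    a = gen_babble(0.5, level, seed=42)
    b = gen_babble(0.5, level + delta, seed=42)
    assert b.rms_spl - a.rms_spl == pytest.approx(delta, abs=1e-8)
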