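"""TNR algorithms: detector, gain dynamics, filterbank, scaling laws."""

import numpy as np
import pytest
import scipy.signal

from tnrlab.audio import AudioSignal
from tnrlab.metrics import attenuation_db
from tnrlab.synth import gen_babble, gen_cafeteria, gen_click_train
from tnrlab.tnr import (DetectorParams, TNRParams, attenuation_for_event,
                        detect_transients, envelope, filterbank_split,
                        filterbank_sum, run_tnr, tnr_broadband, tnr_multiband)

from conftest import CLICK_TIMES

FS = 16_000


class TestEnvelope:
    def test_steady_tone_settles_at_rms(self, tone):
        env = envelope(tone(level_spl=70.0, dur=0.5), smoothing_ms=0.5)
        assert env[-1] == pytest.approx(70.0, abs=0.5)

    def test_silence_sits_at_floor(self):
        env = envelope(AudioSignal(np.zeros(FS)), smoothing_ms=1.0)
        assert np.all(env <= -130.0 + 110.0 + 1e-9)

    def test_db_linearity(self, tone):
        x = tone(level_spl=70.0, dur=0.3)
        e1 = envelope(x)
        e2 = envelope(x.with_samples(2.0 * x.samples))
        np.testing.assert_allclose(e2 - e1, 20 * np.log10(2.0), atol=1e-9)

    def test_invalid_smoothing(self, tone):
        with pytest.raises(ValueError):
            envelope(tone(), smoothing_ms=0.0)


class TestDetector:
    def test_click_above_bed_yields_one_event(self, babble_bed):
        """Oracle: the click time is known by construction; the detector
        must report exactly one event within 2 ms of it."""
        t0 = 1.0
        click = gen_click_train([t0], peak_spl=100.0, duration=5.0)
        x = babble_bed.with_samples(babble_bed.samples + click.samples)
        events = detect_transients(x)
        assert len(events) == 1
        assert events[0].onset_sample / FS == pytest.approx(t0, abs=2e-3)

    def test_slow_ramp_is_not_a_transient(self):
        """A 100 ms ramp of the same height has slope 0.2 dB/ms, below the
        1 dB/ms threshold -> no events."""
        t = np.arange(FS) / FS
        carrier = np.sin(2 * np.pi * 3000 * t)
        amp = 10 ** ((100.0 - 110.0) / 20)
        ramp = np.clip((t - 0.4) / 0.1, 10 ** (-20 / 20), 1.0)
        x = AudioSignal(amp * ramp * carrier)
        assert detect_transients(x) == []

    def test_silence_yields_nothing(self):
        assert detect_transients(AudioSignal(np.zeros(FS))) == []


class TestAttenuationForEvent:
    def test_threshold_level_multiband_is_10_db(self):
        p = TNRParams(scale_atten=1.0)
        thr = p.detector.amp_threshold_db
        assert attenuation_for_event(thr, p, band=2) == pytest.approx(10.0)

    def test_maximal_broadband_at_scale_2_is_60_db(self):
        p = TNRParams(scale_atten=2.0)
        assert attenuation_for_event(50.0, p, band=None) == pytest.approx(60.0)

    def test_scale_zero_gives_zero(self):
        p = TNRParams(scale_atten=0.0)
        assert attenuation_for_event(30.0, p, band=1) == 0.0
        assert attenuation_for_event(30.0, p, band=None) == 0.0

    def test_proportional_map_saturates(self):
        p = TNRParams(scale_atten=1.0)
        thr = p.detector.amp_threshold_db
        assert attenuation_for_event(thr + 20.0, p, band=0) == pytest.approx(30.0)
        assert attenuation_for_event(thr + 80.0, p, band=0) == pytest.approx(30.0)


def _band_peak_reduction(x, y, t0, lo=0.0005, hi=0.0035):
    """Peak meter oracle: 2-7.5 kHz band peaks around the click peak."""
    sos = scipy.signal.butter(4, [2000, 7500], btype="bandpass", fs=FS,
                              output="sos")
    xb = scipy.signal.sosfiltfilt(sos, x.samples)
    yb = scipy.signal.sosfiltfilt(sos, y.samples)
    i0, i1 = int((t0 + lo) * FS), int((t0 + hi) * FS)
    return 20 * np.log10(np.max(np.abs(xb[i0:i1])) / np.max(np.abs(yb[i0:i1])))


class TestBroadband:
    def test_scale_zero_is_bit_identical(self, click_mix):
        res = tnr_broadband(click_mix, TNRParams(scale_atten=0.0))
        assert np.array_equal(res.signal.samples, click_mix.samples)
        assert np.all(res.gain == 1.0)

    def test_click_peak_reduced_by_base_attenuation(self, click_mix):
        res = tnr_broadband(click_mix, TNRParams())
        for t0 in CLICK_TIMES[:4]:
            assert _band_peak_reduction(click_mix, res.signal, t0) == \
                pytest.approx(30.0, abs=3.0)

    def test_gain_recovers_within_5_tau(self, click_mix):
        p = TNRParams()
        res = tnr_broadband(click_mix, p)
        g_db = 20 * np.log10(res.gain)
        for t0 in CLICK_TIMES:
            i = int((t0 + 0.015 + 5 * p.base_tau_ms * 1e-3) * FS)
            assert g_db[i] > -1.0

    def test_determinism(self, click_mix):
        a = tnr_broadband(click_mix, TNRParams())
        b = tnr_broadband(click_mix, TNRParams())
        assert np.array_equal(a.signal.samples, b.signal.samples)

    def test_gain_never_amplifies(self, click_mix):
        res = tnr_broadband(click_mix, TNRParams(scale_atten=2.0, scale_tau=2.0))
        assert np.all(res.gain <= 1.0) and np.all(res.gain > 0.0)


class TestFilterbank:
    def test_split_sum_reconstructs_exactly(self, babble_bed):
        bands = filterbank_split(babble_bed)
        rec = filterbank_sum(bands, babble_bed)
        np.testing.assert_allclose(rec.samples, babble_bed.samples,
                                   atol=1e-12)

    @pytest.mark.parametrize("freq,expected_band", [
        (500.0, 0), (1500.0, 1), (3000.0, 2), (6000.0, 3)])
    def test_tone_energy_lands_in_its_band(self, tone, freq, expected_band):
        x = tone(level_spl=75.0, freq=freq, dur=0.5)
        bands = filterbank_split(x)
        energies = np.array([np.sum(b**2) for b in bands])
        assert energies[expected_band] / energies.sum() >= 0.95

    def test_band_isolation_one_octave_out(self, tone):
        x = tone(level_spl=75.0, freq=2000.0, dur=0.5)
        bands = filterbank_split(x)
        # 2 kHz is one octave above band 1's top edge -> >= 30 dB down there
        leak = 10 * np.log10(np.sum(bands[0] ** 2) / np.sum(x.samples**2))
        assert leak <= -30.0

    def test_edge_above_nyquist_rejected(self, babble_bed):
        with pytest.raises(ValueError):
            filterbank_split(babble_bed, (0.0, 1000.0, 9000.0))


class TestMultiband:
    def test_scale_zero_equals_roundtrip(self, click_mix):
        res = tnr_multiband(click_mix, TNRParams(scale_atten=0.0))
        rt = filterbank_sum(filterbank_split(click_mix), click_mix)
        np.testing.assert_array_equal(res.signal.samples, rt.samples)

    def test_click_reduction_in_proportional_range(self, click_mix):
        res = tnr_multiband(click_mix, TNRParams())
        for t0 in CLICK_TIMES[:4]:
            red = _band_peak_reduction(click_mix, res.signal, t0)
            assert 10.0 <= red <= 33.0

    def test_high_band_click_leaves_low_band_alone(self, tone):
        """Click at 6 kHz + low-band speech tone: band-4 gain dips, band-1
        gain stays within 1 dB of unity."""
        speech = tone(level_spl=75.0, freq=400.0, dur=3.0)
        click = gen_click_train([1.5], peak_spl=100.0, duration=3.0,
                                freqs_hz=(6000.0, 6800.0))
        x = speech.with_samples(speech.samples + click.samples)
        res = tnr_multiband(x, TNRParams())
        g_db = 20 * np.log10(res.gain)
        assert g_db[3].min() < -10.0
        assert g_db[0].min() > -1.0

    def test_events_report_their_band(self, click_mix):
        res = tnr_multiband(click_mix, TNRParams())
        bands = {e.band_index for e in res.events}
        assert bands <= {0, 1, 2, 3} and (2 in bands or 3 in bands)


class TestScalingLaws:
    @pytest.mark.parametrize("axis", ["scale_atten", "scale_tau"])
    def test_total_attenuation_monotone_in_scales(self, cafeteria, axis):
        """On fixed seeded cafeteria noise the applied rms attenuation is
        non-decreasing in each scaling factor."""
        prev = 0.1
        for s in (0.0, 0.5, 1.0, 1.5, 2.0):
            p = TNRParams(**{axis: s})
            a = attenuation_db(cafeteria, tnr_broadband(cafeteria, p).signal)
            assert a <= prev + 1e-6
            prev = a

    def test_scales_clamped_to_limits(self):
        p = TNRParams(scale_atten=5.0, scale_tau=-1.0)
        assert p.scale_atten == 2.0 and p.scale_tau == 0.0

    def test_full_spectrum_transient_aligns_variants(self):
        """With the proportional map disabled and equal per-band tau, the
        multiband output of a broadband (white) transient approaches the
        broadband output (within 1 dB rms over the event)."""
        bed = gen_babble(5.0, 60.0, seed=1)
        rng = np.random.default_rng(8)
        n_ev = int(0.004 * FS)
        env = np.exp(-np.arange(n_ev) / (0.003 * FS))
        env[: 16] *= np.linspace(0, 1, 16)
        burst = rng.standard_normal(n_ev) * env
        burst *= 10 ** ((110.0 - 110.0) / 20) / np.abs(burst).max()
        samples = bed.samples.copy()
        samples[FS: FS + n_ev] += burst
        x = bed.with_samples(samples)
        p = TNRParams(proportional=False, band_tau_ms=(30.0,) * 4)
        resb = tnr_broadband(x, p)
        resm = tnr_multiband(x, p)
        assert {e.band_index for e in resm.events} == {0, 1, 2, 3}
        seg = slice(int(0.999 * FS), int(1.05 * FS))
        rb = 20 * np.log10(np.std(resb.signal.samples[seg]))
        rm = 20 * np.log10(np.std(resm.signal.samples[seg]))
        assert abs(rb - rm) < 1.0

    def test_run_tnr_dispatch(self, click_mix):
        off = run_tnr(click_mix, "off", TNRParams())
        assert np.array_equal(off.signal.samples, click_mix.samples)
        with pytest.raises(ValueError):
            run_tnr(click_mix, "nope", TNRParams())
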