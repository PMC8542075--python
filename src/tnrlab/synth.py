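"""Synthetic audio: cafeteria noise, matrix-style sentences, SNR mixing.

The study conditions this package targets use a "cafeteria" noise — a
stationary multi-talker babble bed with randomly timed, high-intensity
dish-clatter transients (~1 ms onsets) — presented at a calibrated 80 dB
SPL-equivalent rms, and closed-set five-word matrix sentences
(name-verb-numeral-color-object).  Neither the original noise recording nor
the licensed sentence corpus is redistributable, so this module synthesizes
surrogates with the stated statistics:

* babble: speech-shaped Gaussian noise (LTASS-like, -9 dB/octave above
  500 Hz) with a slow ~4 Hz amplitude modulation.  Synthesis is done by
  shaping the FFT of white noise, which makes the waveform exactly periodic
  and therefore loopable without a click.
* clatter: Poisson-timed damped two-resonance bursts (2-6 kHz) with a
  configurable rise time, emulating dish impacts whose energy sits largely
  above the speech band.
* sentences: five concatenated word tokens, each a harmonic complex plus a
  noise floor whose parameters encode the (slot, word) identity, so a
  simulated listener can be scored per word.

All generators are seed-deterministic and calibrated in dB SPL-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import DEFAULT_RATE, DEFAULT_SPL_REF, AudioSignal, db_to_amp

__all__ = [
    "NoiseRecipe",
    "SentenceTokens",
    "WORD_INVENTORY",
    "gen_babble",
    "gen_clatter",
    "gen_click_train",
    "gen_cafeteria",
    "gen_sentence",
    "gen_speech_track",
    "mix_at_snr",
]


# --------------------------------------------------------------------------
# babble
# --------------------------------------------------------------------------

def speech_shape(freqs_hz: np.ndarray) -> np.ndarray:
    """LTASS-like magnitude template (linear amplitude, unnormalized).

    Flat from 100 to 500 Hz, -9 dB/octave above 500 Hz, -12 dB/octave
    roll-off below 100 Hz to keep DC/infrasound energy out.
    """
    f = np.maximum(np.asarray(freqs_hz, dtype=float), 1e-3)
    mag = np.ones_like(f)
    hi = f > 500.0
    mag[hi] = db_to_amp(-9.0) ** np.log2(f[hi] / 500.0)
    lo = f < 100.0
    mag[lo] = db_to_amp(-12.0) ** np.log2(100.0 / f[lo])
    mag[freqs_hz <= 0] = 0.0
    return mag


def _shaped_noise(n: int, rate: int, rng: np.random.Generator,
                  shape_fn) -> np.ndarray:
    """Gaussian noise with the given rfft magnitude shape (periodic)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    spec *= shape_fn(np.fft.rfftfreq(n, d=1.0 / rate))
    return np.fft.irfft(spec, n)


def gen_babble(
    duration: float,
    level_spl: float = 80.0,
    seed: int | None = None,
    rate: int = DEFAULT_RATE,
    spl_ref: float = DEFAULT_SPL_REF,
    am_rate_hz: float = 4.0,
    am_depth: float = 0.3,
) -> AudioSignal:
    """Speech-shaped babble surrogate with slow amplitude modulation.

    The modulator is itself periodic band-limited noise (0.5 Hz to
    ~2 x ``am_rate_hz``), so the output loops cleanly end-to-end.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    x = _shaped_noise(n, rate, rng, speech_shape)
    if am_depth > 0:
        mod = _shaped_noise(
            n, rate, rng,
            lambda f: ((f >= 0.5) & (f <= 2.0 * am_rate_hz)).astype(float),
        )
        sd = mod.std()
        if sd > 0:
            mod = mod / sd
        x = x * (1.0 + am_depth * np.clip(mod, -2.5, 2.5) / 2.5)
    return AudioSignal(x, rate=rate, spl_ref=spl_ref).scaled_to_spl(level_spl)


# --------------------------------------------------------------------------
# clatter
# --------------------------------------------------------------------------

@dataclass
class NoiseRecipe:
    """Parameters of the transient (dish-clatter) component.

    ``level_spl`` is the rms level of the babble bed the transients will sit
    in; ``peak_excess_db`` sets the event waveform peak that many dB above
    the bed rms.  Events are Poisson-timed at ``transient_rate`` per second.
    Transients by definition decay within one second, which bounds the
    decay constants.
    """

    duration: float = 5.0
    level_spl: float = 80.0
    transient_rate: float = 2.0
    onset_ms: float = 1.0
    peak_excess_db: float = 20.0
    peak_jitter_db: float = 3.0
    decay_ms_range: tuple[float, float] = (15.0, 60.0)
    freq_range_hz: tuple[float, float] = (2000.0, 6000.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset_ms <= 0:
            raise ValueError("onset_ms must be positive")
        if self.onset_ms > 1000.0:
            raise ValueError("onset_ms must not exceed 1000 ms")
        if self.peak_excess_db < 0:
            raise ValueError("peak_excess_db must be non-negative")
        if self.transient_rate < 0:
            raise ValueError("transient_rate must be non-negative")
        # full event (rise + 8 decay constants) must fit inside one second
        if self.onset_ms + 8.0 * self.decay_ms_range[1] > 1000.0:
            raise ValueError("event span would exceed the 1 s transient bound")


def _burst(rate: int, onset_ms: float, decay_ms: float,
           freqs_hz: tuple[float, float], phases: tuple[float, float],
           peak_amp: float) -> np.ndarray:
    """One damped two-resonance burst with a raised-cosine rise."""
    n_rise = max(int(round(onset_ms * 1e-3 * rate)), 1)
    n_tail = int(round(8.0 * decay_ms * 1e-3 * rate))
    n = n_rise + n_tail
    t = np.arange(n) / rate
    env = np.ones(n)
    env[:n_rise] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_rise) / n_rise))
    env[n_rise:] = np.exp(-(t[n_rise:] - t[n_rise]) / (decay_ms * 1e-3))
    w = env * (
        np.sin(2 * np.pi * freqs_hz[0] * t + phases[0])
        + 0.6 * np.sin(2 * np.pi * freqs_hz[1] * t + phases[1])
    )
    m = np.max(np.abs(w))
    return w * (peak_amp / m) if m > 0 else w


def _synth_clatter(recipe: NoiseRecipe, rate: int, spl_ref: float):
    """Return (samples, onset_times_s) of the clatter track alone."""
    n = int(round(recipe.duration * rate))
    out = np.zeros(n)
    rng = np.random.default_rng(recipe.seed)
    n_events = rng.poisson(recipe.transient_rate * recipe.duration)
    bed_rms = db_to_amp(recipe.level_spl - spl_ref)
    onsets = []
    max_span = (recipe.onset_ms + 8.0 * recipe.decay_ms_range[1]) * 1e-3
    t_max = max(recipe.duration - max_span, 0.0)
    for _ in range(n_events):
        t0 = rng.uniform(0.0, t_max)
        decay = rng.uniform(*recipe.decay_ms_range)
        f1 = rng.uniform(*recipe.freq_range_hz)
        f2 = np.clip(f1 * rng.uniform(1.2, 1.6), *recipe.freq_range_hz)
        excess = recipe.peak_excess_db + rng.uniform(
            -recipe.peak_jitter_db, recipe.peak_jitter_db
        )
        w = _burst(rate, recipe.onset_ms, decay, (f1, f2),
                   tuple(rng.uniform(0, 2 * np.pi, 2)),
                   bed_rms * db_to_amp(excess))
        i0 = int(round(t0 * rate))
        i1 = min(i0 + len(w), n)
        out[i0:i1] += w[: i1 - i0]
        onsets.append(t0)
    return out, sorted(onsets)


def gen_clatter(
    recipe: NoiseRecipe,
    rate: int = DEFAULT_RATE,
    spl_ref: float = DEFAULT_SPL_REF,
    with_events: bool = False,
):
    """Poisson-timed dish-clatter transients (no babble bed).

    Returns the :class:`AudioSignal`; with ``with_events=True`` also the
    sorted list of event onset times in seconds.
    """
    samples, onsets = _synth_clatter(recipe, rate, spl_ref)
    sig = AudioSignal(samples, rate=rate, spl_ref=spl_ref)
    return (sig, onsets) if with_events else sig


def gen_click_train(
    times_s,
    peak_spl: float,
    duration: float | None = None,
    onset_ms: float = 1.0,
    decay_ms: float = 3.0,
    freqs_hz: tuple[float, float] = (3000.0, 4500.0),
    rate: int = DEFAULT_RATE,
    spl_ref: float = DEFAULT_SPL_REF,
) -> AudioSignal:
    """Deterministic train of identical fast-onset clicks at given times.

    Useful as a controlled probe: every click has the configured rise time
    and its waveform peak calibrated to ``peak_spl`` dB SPL-equivalent.
    """
    times_s = np.atleast_1d(np.asarray(times_s, dtype=float))
    if duration is None:
        duration = float(times_s.max()) + onset_ms * 1e-3 + 10 * decay_ms * 1e-3
    n = int(round(duration * rate))
    out = np.zeros(n)
    peak_amp = db_to_amp(peak_spl - spl_ref)
    w = _burst(rate, onset_ms, decay_ms, freqs_hz, (0.3, 1.1), peak_amp)
    for t0 in times_s:
        i0 = int(round(t0 * rate))
        i1 = min(i0 + len(w), n)
        out[i0:i1] += w[: i1 - i0]
    return AudioSignal(out, rate=rate, spl_ref=spl_ref)


def gen_cafeteria(
    duration: float = 5.0,
    level_spl: float = 80.0,
    seed: int | None = None,
    rate: int = DEFAULT_RATE,
    spl_ref: float = DEFAULT_SPL_REF,
    transient_rate: float = 2.0,
    peak_excess_db: float = 20.0,
    with_events: bool = False,
):
    """Cafeteria noise: babble bed plus clatter, calibrated as a whole.

    The total rms is calibrated to ``level_spl``; the relative excess of the
    transient peaks over the bed is preserved by the common rescale.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_babble, s_clatter = ss.spawn(2)
    bed = gen_babble(duration, level_spl, seed=s_babble, rate=rate,
                     spl_ref=spl_ref)
    recipe = NoiseRecipe(
        duration=duration, level_spl=level_spl,
        transient_rate=transient_rate, peak_excess_db=peak_excess_db,
        seed=s_clatter,
    )
    clatter, onsets = _synth_clatter(recipe, rate, spl_ref)
    sig = AudioSignal(bed.samples + clatter, rate=rate, spl_ref=spl_ref)
    sig = sig.scaled_to_spl(level_spl)
    return (sig, onsets) if with_events else sig


# --------------------------------------------------------------------------
# matrix-style sentences
# --------------------------------------------------------------------------

#: Closed slot inventories of the matrix-style surrogate corpus
#: (name-verb-numeral-color-object, 10 alternatives per slot).
WORD_INVENTORY: tuple[tuple[str, ...], ...] = (
    ("david", "ellen", "emma", "jacob", "johan",
     "lucas", "mila", "peter", "sara", "thomas"),
    ("buys", "draws", "finds", "gets", "gives",
     "has", "keeps", "sees", "takes", "wins"),
    ("two", "three", "four", "five", "six",
     "seven", "eight", "nine", "ten", "twelve"),
    ("black", "blue", "brown", "green", "grey",
     "pink", "purple", "red", "white", "yellow"),
    ("bags", "beds", "boats", "books", "chairs",
     "cloths", "cups", "desks", "rings", "shoes"),
)


@dataclass
class SentenceTokens:
    """Scoring tokens for one five-word sentence."""

    words: tuple[str, ...]
    onsets: tuple[float, ...]
    indices: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.words) != 5 or len(self.onsets) != 5:
            raise ValueError("a matrix sentence has exactly 5 words")
        if not all(b > a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("word onsets must be strictly increasing")


def _word_waveform(slot: int, idx: int, rate: int, dur_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Spectro-temporally coded word token.

    A harmonic complex whose fundamental encodes the word index and whose
    spectral centroid encodes the slot, plus a -15 dB band-limited noise
    floor so every token has broadband content.  20 ms raised-cosine rise
    and fall; every other word starts with a plosive-like consonant burst
    (a few ms of fast-onset noise), the feature that makes natural speech
    susceptible to transient-noise-reduction distortion.
    """
    n = int(round(dur_s * rate))
    t = np.arange(n) / rate
    f0 = 120.0 + 14.0 * idx + 3.0 * slot
    centroid = 300.0 * 2.0 ** (0.45 * slot)
    w = np.zeros(n)
    for h in range(1, 30):
        f = f0 * h
        if f > 0.45 * rate:
            break
        amp = 1.0 / (1.0 + (f / centroid) ** 2) * (f / f0) ** 0.3
        w += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    noise = _shaped_noise(
        n, rate, rng, lambda f: ((f >= 300.0) & (f <= 5000.0)).astype(float)
    )
    w = w / (np.sqrt(np.mean(w**2)) + 1e-12)
    noise = noise / (np.sqrt(np.mean(noise**2)) + 1e-12)
    w = w + db_to_amp(-15.0) * noise
    n_ramp = min(int(0.020 * rate), n // 2)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    w[:n_ramp] *= ramp
    w[-n_ramp:] *= ramp[::-1]
    if idx % 2 == 0:
        # plosive onset: 1 ms rise, ~4 ms decay, 1-6 kHz burst, +10 dB peak
        burst = _burst(rate, 1.0, 4.0,
                       (1000.0 + 500.0 * slot, 2500.0 + 700.0 * slot),
                       tuple(rng.uniform(0, 2 * np.pi, 2)),
                       db_to_amp(10.0))
        m = min(len(burst), n)
        w[:m] += burst[:m]
    return w


def gen_sentence(
    level_spl: float = 77.0,
    seed: int | None = None,
    rate: int = DEFAULT_RATE,
    spl_ref: float = DEFAULT_SPL_REF,
    word_dur_s: float = 0.35,
    gap_s: float = 0.05,
) -> tuple[AudioSignal, SentenceTokens]:
    """One five-word matrix-style sentence with per-word onset times."""
    rng = np.random.default_rng(seed)
    idx = tuple(int(i) for i in rng.integers(0, 10, size=5))
    words = tuple(WORD_INVENTORY[s][i] for s, i in enumerate(idx))
    chunks, onsets = [], []
    t = 0.0
    for s, i in enumerate(idx):
        onsets.append(t)
        chunks.append(_word_waveform(s, i, rate, word_dur_s, rng))
        t += word_dur_s
        if s < 4:
            chunks.append(np.zeros(int(round(gap_s * rate))))
            t += gap_s
    sig = AudioSignal(np.concatenate(chunks), rate=rate, spl_ref=spl_ref)
    sig = sig.scaled_to_spl(level_spl)
    return sig, SentenceTokens(words, tuple(onsets), idx)


def gen_speech_track(
    n_sentences: int = 20,
    level_spl: float = 77.0,
    seed: int | None = None,
    rate: int = DEFAULT_RATE,
    spl_ref: float = DEFAULT_SPL_REF,
    pause_s: float = 0.1,
) -> AudioSignal:
    """Concatenate random sentences into a characterization speech file.

    Twenty sentences yield roughly 40 s of material.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    parts = []
    gap = np.zeros(int(round(pause_s * rate)))
    for child in ss.spawn(n_sentences):
        sig, _ = gen_sentence(level_spl, seed=child, rate=rate,
                              spl_ref=spl_ref)
        parts.extend((sig.samples, gap))
    out = AudioSignal(np.concatenate(parts[:-1]), rate=rate, spl_ref=spl_ref)
    return out.scaled_to_spl(level_spl)


# --------------------------------------------------------------------------
# mixing
# --------------------------------------------------------------------------

def mix_at_snr(
    speech: AudioSignal,
    noise: AudioSignal,
    snr_db: float,
    lead_s: float = 1.5,
) -> AudioSignal:
    """Mix speech into noise at a given SNR with a noise-only lead-in.

    The noise keeps its own calibrated level; the speech is rescaled so that
    over the overlap region speech rms - noise rms = ``snr_db``.  The noise
    is looped if shorter than lead + speech.  ``snr_db = +inf`` is a
    sentinel for "no noise": the output is the speech padded by the lead.
    """
    if speech.rate != noise.rate:
        raise ValueError("speech and noise sample rates differ")
    n_lead = int(round(lead_s * speech.rate))
    total = n_lead + len(speech)
    if np.isinf(snr_db) and snr_db > 0:
        out = np.zeros(total)
        out[n_lead:] = speech.samples
        return speech.with_samples(out)
    noise_full = noise.loop_to(total / noise.rate)
    # the SNR contract holds over the overlap region, so the reference is
    # the noise rms there (an excerpt can sit off the global level)
    overlap_rms_spl = AudioSignal(noise_full.samples[n_lead:],
                                  rate=noise.rate,
                                  spl_ref=noise.spl_ref).rms_spl
    sp = speech.scaled_to_spl(overlap_rms_spl + snr_db)
    out = noise_full.samples.copy()
    out[n_lead:] += sp.samples
    return AudioSignal(out, rate=speech.rate, spl_ref=speech.spl_ref)
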