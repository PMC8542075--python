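"""Calibrated mono audio container and level arithmetic.

Every DSP stage in the package trades in :class:`AudioSignal`: a mono sample
sequence in full-scale units together with its sample rate and an SPL
calibration.  The calibration convention is that a signal with an rms of
0 dBFS corresponds to ``spl_ref`` dB SPL-equivalent, so a typical 80 dB
SPL-equivalent noise sits around -30 dBFS and is safely below clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.io.wavfile

DEFAULT_RATE = 16_000
#: dB SPL-equivalent of a 0 dBFS-rms signal (full scale).
DEFAULT_SPL_REF = 110.0

_EPS = 1e-30


def db_to_amp(db: float) -> float:
    """Convert a level difference in dB to a linear amplitude factor."""
    return 10.0 ** (db / 20.0)


def amp_to_db(amp) -> float:
    """Convert a linear amplitude (ratio) to dB. Zero maps to -inf."""
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(np.maximum(np.asarray(amp, dtype=float), 0.0))


@dataclass
class AudioSignal:
    """Mono audio with a sample rate and an SPL-equivalent calibration.

    Parameters
    ----------
    samples:
        1-D float array in full-scale units.
    rate:
        Sample rate in Hz (> 0).
    spl_ref:
        dB SPL-equivalent corresponding to a 0 dBFS rms.
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE
    spl_ref: float = DEFAULT_SPL_REF

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self) / self.rate

    @property
    def rms(self) -> float:
        """Linear rms in full-scale units."""
        if len(self) == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def rms_dbfs(self) -> float:
        return float(amp_to_db(max(self.rms, _EPS)))

    @property
    def rms_spl(self) -> float:
        """rms level on the calibrated dB SPL-equivalent scale."""
        return self.spl_ref + self.rms_dbfs

    def with_samples(self, samples: np.ndarray) -> "AudioSignal":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    def gain_db(self, db: float) -> "AudioSignal":
        return self.with_samples(self.samples * db_to_amp(db))

    def scaled_to_spl(self, level_spl: float) -> "AudioSignal":
        """Rescale so the rms sits at ``level_spl`` dB SPL-equivalent."""
        if self.rms <= 0.0:
            raise ValueError("cannot calibrate a silent signal")
        return self.gain_db(level_spl - self.rms_spl)

    def loop_to(self, duration_s: float) -> "AudioSignal":
        """Tile the signal (no crossfade) to at least ``duration_s`` seconds
        and truncate to exactly that length."""
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        n = int(round(duration_s * self.rate))
        reps = int(np.ceil(n / max(len(self), 1)))
        return self.with_samples(np.tile(self.samples, reps)[:n])

    def same_grid(self, other: "AudioSignal") -> bool:
        return self.rate == other.rate and self.spl_ref == other.spl_ref


def read_wav(path, spl_ref: float = DEFAULT_SPL_REF) -> AudioSignal:
    """Read a mono WAV file (PCM or float) into an :class:`AudioSignal`."""
    rate, data = scipy.io.wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return AudioSignal(data.astype(np.float64), rate=rate, spl_ref=spl_ref)


def write_wav(path, signal: AudioSignal) -> None:
    """Write as 32-bit float WAV (full-scale units preserved)."""
    scipy.io.wavfile.write(path, signal.rate, signal.samples.astype(np.float32))
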