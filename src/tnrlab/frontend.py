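"""Simulated CI front end: preemphasis, dual-loop AGC, and chain wiring.

The processing chain emulated here is the experimental variant of a CI
sound-coding front end in which the TNR stage and the broadband dual-loop
AGC run in software while the speech processor itself still applies its
own (non-defeatable) preemphasis.  To keep the overall transfer correct,
the AGC gain is computed on a preemphasized branch of the TNR output but
applied to the non-preemphasized TNR output; the processor's preemphasis
then acts once on the result.

The dual-loop AGC combines a slow, high-ratio loop (gradual overall level
adaptation) with a fast, moderate-ratio loop (3-5 ms attack) by taking the
minimum of the two gains.  The published description gives no numeric
constants, so the defaults below are representative and configurable:
slow {240 ms attack, 1500 ms release, 63 dB SPL knee, 12:1} and fast
{4 ms, 80 ms, 71 dB SPL, 3:1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from . import _kernels
from .audio import AudioSignal
from .tnr import ENV_FLOOR_DB, TNRParams, TNRResult, run_tnr

__all__ = [
    "LoopParams",
    "AGCParams",
    "ChainConfig",
    "preemphasis",
    "loop_gain_db",
    "agc_gain",
    "apply_chain",
]

VARIANTS = ("off", "bb_std", "bb", "mb")


@dataclass
class LoopParams:
    """One AGC detector loop: first-order attack/release dynamics feeding a
    knee/ratio static compression curve."""

    attack_ms: float
    release_ms: float
    knee_spl: float
    ratio: float

    def __post_init__(self) -> None:
        if self.attack_ms <= 0 or self.release_ms <= 0:
            raise ValueError("attack and release must be positive")
        if self.ratio < 1:
            raise ValueError("compression ratio must be >= 1")


@dataclass
class AGCParams:
    slow: LoopParams = field(
        default_factory=lambda: LoopParams(240.0, 1500.0, 63.0, 12.0))
    fast: LoopParams = field(
        default_factory=lambda: LoopParams(4.0, 80.0, 71.0, 3.0))
    combination: str = "min"


@dataclass
class ChainConfig:
    """Configuration of the full simulated front end."""

    tnr_variant: str = "off"
    tnr_params: TNRParams = field(default_factory=TNRParams)
    agc: AGCParams = field(default_factory=AGCParams)
    agc_enabled: bool = True
    preemphasis_corner_hz: float = 1200.0

    def __post_init__(self) -> None:
        if self.tnr_variant not in VARIANTS:
            raise ValueError(
                f"tnr_variant must be one of {VARIANTS}, got {self.tnr_variant!r}")


def preemphasis(x: AudioSignal, corner_hz: float = 1200.0) -> AudioSignal:
    """First-order high-pass preemphasis (6 dB/octave below the corner).

    DC is rejected entirely, satisfying the >= 40 dB DC attenuation
    contract by construction.
    """
    b, a = scipy.signal.butter(1, corner_hz, btype="highpass", fs=x.rate)
    return x.with_samples(scipy.signal.lfilter(b, a, x.samples))


def _coeff(fs: float, tau_ms: float) -> float:
    return 1.0 - float(np.exp(-1.0 / (fs * tau_ms * 1e-3)))


def loop_gain_db(x: AudioSignal, loop: LoopParams) -> np.ndarray:
    """Per-sample gain (dB <= 0) of a single detector loop.

    The level detector is a short symmetric rms smoother (2 ms, which
    removes the 2f power ripple of tonal inputs without biasing the level)
    followed by an attack/release one-pole; the static curve is unity below
    the knee and slope 1/ratio above it.
    """
    floor_p = 10.0 ** (ENV_FLOOR_DB / 10.0)
    p = x.samples**2
    init = float(p[: max(int(x.rate * 0.005), 1)].mean()) if len(x) else 0.0
    p = _kernels.one_pole_power(p, _coeff(x.rate, 2.0), init, floor_p)
    det = _kernels.asym_one_pole_power(
        p, _coeff(x.rate, loop.attack_ms), _coeff(x.rate, loop.release_ms),
        init, floor_p,
    )
    level_spl = x.spl_ref + 10.0 * np.log10(det)
    over = np.maximum(level_spl - loop.knee_spl, 0.0)
    return -over * (1.0 - 1.0 / loop.ratio)


def agc_gain(x: AudioSignal, p: AGCParams | None = None) -> np.ndarray:
    """Per-sample linear gain of the dual-loop AGC (in (0, 1]).

    The combined gain is the minimum of the slow- and fast-loop gains.
    """
    p = p or AGCParams()
    if p.combination != "min":
        raise ValueError(f"unknown combination rule {p.combination!r}")
    gdb = np.minimum(loop_gain_db(x, p.slow), loop_gain_db(x, p.fast))
    return 10.0 ** (gdb / 20.0)


def apply_chain(x: AudioSignal, c: ChainConfig | None = None,
                return_parts: bool = False):
    """Run TNR -> AGC (with the preemphasis bypass) -> processor preemphasis.

    The AGC gain is computed on ``preemphasis(tnr_out)`` and applied,
    sample for sample, to the non-preemphasized TNR output; the processor's
    own preemphasis then acts on the gained signal.  With the TNR off and
    the AGC disabled the chain reduces to ``preemphasis(x)``.

    With ``return_parts=True`` returns ``(output, tnr_result, agc_gains)``.
    """
    c = c or ChainConfig()
    tnr_res: TNRResult = run_tnr(x, c.tnr_variant, c.tnr_params)
    y = tnr_res.signal
    if c.agc_enabled:
        g = agc_gain(preemphasis(y, c.preemphasis_corner_hz), c.agc)
        y = y.with_samples(y.samples * g)
    else:
        g = np.ones(len(y))
    out = preemphasis(y, c.preemphasis_corner_hz)
    if return_parts:
        return out, tnr_res, g
    return out
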