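# tnrlab

Simulation toolkit for **transient noise reduction (TNR) in cochlear-implant
front ends**: broadband and multiband TNR with personalizable attenuation and
release time, the simulated CI signal chain they sit in (preemphasis +
dual-loop AGC), noise-attenuation/speech-distortion metrics, adaptive
speech-reception-threshold (SRT) testing with simulated listeners, and
preference-driven parameter personalization — all exercised end-to-end on
synthetic audio.

## The problem

Transient noise — dish clatter, door slams: sounds with ~1 ms onsets, fast
decay, and durations under a second — is disruptive for cochlear-implant
users, whose speech understanding in noise is fragile to begin with.  TNR
algorithms monitor the slope and amplitude of the signal envelope and briefly
attenuate the signal when a transient is detected.  Two design parameters
dominate the behaviour:

* the **attenuation** applied on detection (base 30 dB), and
* the **release time** τ governing how long the attenuation persists
  (base 30 ms broadband; 30–40 ms per band multiband).

Both are personalized through scaling factors in [0, 2], so attenuation
spans 0–60 dB and τ spans 0–60 ms (0–80 ms for the lowest band).  The
**broadband** variant (`bb`) attenuates the full signal by a fixed
scaled amount; the **multiband** variant (`mb`) splits the signal into four
bands (0–1, 1–2, 2–4, >4 kHz), detects per band, and applies an attenuation
proportional to the band-specific transient amplitude (10 dB at threshold
level up to 30 dB), confining the damage to the bands that actually carry
the transient.  `bb_std` is `bb` pinned at scales (1, 1); `off` is the
pass-through control.

Because the original study's audio (licensed matrix sentences, a recorded
cafeteria noise) and its human listeners are not available, the package
ships a first-class synthetic-data module: calibrated speech-shaped babble
with Poisson-timed dish-clatter bursts, five-word matrix-style sentence
surrogates with per-word scoring tokens, and logistic-psychometric
simulated listeners.

## Worked example

```python
import numpy as np
from tnrlab import (gen_babble, gen_click_train, TNRParams,
                    tnr_broadband, tnr_multiband, attenuation_db,
                    third_octave_coherence)

bed = gen_babble(5.0, 80.0, seed=1)                 # 80 dB SPL-eq babble
clicks = gen_click_train(np.arange(0.5, 4.6, 0.4),  # 1 ms-onset clicks,
                         peak_spl=100.0, duration=5.0)  # 20 dB above bed
mix = bed.with_samples(bed.samples + clicks.samples)

res = tnr_broadband(mix, TNRParams(scale_atten=1.0, scale_tau=1.0))
print(f"noise level change: {attenuation_db(mix, res.signal):.2f} dB")
print(f"events detected: {len(res.events)}")
print(f"deepest gain: {20*np.log10(res.gain.min()):.1f} dB")
```

prints

```
noise level change: -0.66 dB
events detected: 11
deepest gain: -30.0 dB
```

Eleven clicks are detected and each is pushed down by the full 30 dB
(scale 1 × 30 dB base); the 5-s rms only drops 0.66 dB because the
attenuation is active for tens of milliseconds per event.  (The level
change uses the characterization convention `10·log10(rms_out/rms_in)`;
pass `convention="conventional"` for the amplitude-ratio factor 20.)

The same comparison for the multiband variant shows the design trade-off:

```python
from tnrlab import characterize
table = characterize("mb", (np.array([0.0, 1.0, 2.0]), np.array([1.0])))
print(table[["scale_atten", "noise_atten_db", "weighted_coherence"]])
```

coherence (1 = undistorted speech) decreases as the attenuation scale
grows, and at matched settings the multiband variant keeps a higher speech
coherence than the broadband one while attenuating the noise comparably.

A thin CLI mirrors the library:
`tnrlab gen`, `tnrlab process`, `tnrlab detect`, `tnrlab characterize`,
`tnrlab srt`, `tnrlab personalize`, `tnrlab group-settings`,
`tnrlab experiment` (see `--help` on each).

## Layout

| module | contents |
| --- | --- |
| `tnrlab.audio` | calibrated `AudioSignal` container, WAV I/O |
| `tnrlab.synth` | babble, clatter, cafeteria noise, sentences, SNR mixing |
| `tnrlab.tnr` | detector, broadband/multiband TNR, filterbank |
| `tnrlab.frontend` | preemphasis, dual-loop AGC, chain wiring |
| `tnrlab.metrics` | rms/attenuation, weighted ⅓-octave coherence, sweeps |
| `tnrlab.listener` | psychometric listeners, adaptive SRT staircase |
| `tnrlab.personalization` | range-halving personalization, group settings |
| `tnrlab.experiment` | full in-silico study orchestration |

See `docs/methods.md` for the models, parameter choices and limitations.
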