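# Methods

This note documents the models implemented in `tnrlab`, the parameter
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions that shape the results.

## Signal representation and calibration

All audio is mono float64 at 16 kHz by default (configurable).  16 kHz keeps
the top TNR band a proper 4–8 kHz band below Nyquist while covering the
0–8 kHz range that matters for CI sound coding.  Levels are expressed as dB
SPL-equivalent through a single convention: a 0 dBFS-rms signal corresponds
to `spl_ref` = 110 dB SPL-eq, so the standard 80 dB SPL-eq noise sits at
−30 dBFS rms, clip-safe even with 20 dB transient peaks on top.

## Synthetic cafeteria noise

The noise emulates a cafeteria: a stationary babble bed with randomly timed
dish-clatter transients, calibrated to 80 dB SPL-eq total rms.

* **Babble** — Gaussian noise shaped in the frequency domain to an
  LTASS-like template (flat 100–500 Hz, −9 dB/octave above 500 Hz,
  −12 dB/octave below 100 Hz) with a gentle ~4 Hz amplitude modulation
  (depth 0.3).  FFT-domain synthesis makes the waveform exactly periodic,
  so the canonical 5-s file loops to any length without a click and without
  level change.
* **Clatter** — event count Poisson with rate 2/s; each event is an
  exponentially damped two-resonance burst (resonances drawn from
  2–6 kHz, decay constants 15–60 ms, raised-cosine rise of 1 ms by
  default) whose waveform peak sits 20 ± 3 dB above the bed rms.  The
  2–6 kHz placement concentrates transient energy above the speech band,
  which is exactly the regime in which multiband processing can act
  selectively.  Rise + 8 decay constants always fit within the 1-s
  definition of a transient.  The 20 dB peak excess encodes the "loud
  clatter over a damped murmur" character of the target noise; transients
  much weaker than that are not what a clinical TNR is tuned to suppress.

* **Speech surrogates** — five-word matrix-style sentences
  (name–verb–numeral–color–object, 10 closed alternatives per slot).  Each
  word token is a harmonic complex whose fundamental encodes the word index
  and whose spectral centroid encodes the slot, plus a −15 dB broadband
  noise floor; every other word carries a plosive-like onset (1 ms rise,
  ~4 ms noise burst, +10 dB over the word rms).  The plosives matter: they
  are the feature of natural speech that a transient detector can confuse
  with noise, and without them speech distortion would be structurally
  absent from the characterization.  Twenty concatenated sentences give the
  ~40-s characterization speech file.

What the surrogates do **not** emulate: reverberation, talker identity and
prosody, coarticulation, and the true spectro-temporal statistics of the
licensed matrix corpus.  Tests passing on these surrogates show the
*machinery* behaves correctly (calibration, detection, scaling laws,
procedure logic); they do not predict absolute intelligibility or absolute
distortion values for real recordings.

## Transient detection and gain control

One detector serves both TNR variants.  The envelope is one-pole-smoothed
instantaneous power (0.5 ms), expressed in dB.  An event requires three
simultaneous conditions:

1. envelope slope ≥ 1 dB/ms (measured over a 1 ms window) — ordinary
   speech onsets rise an order of magnitude slower;
2. envelope ≥ background + 12 dB, where the background is a 200 ms
   one-pole average of the power, frozen whenever the envelope is more
   than 6 dB above it so an event cannot inflate its own reference;
3. envelope ≥ 82 dB SPL-eq in absolute terms.  The absolute criterion
   encodes that the algorithm targets *high-intensity* transients; without
   it, a per-band detector in a quiet band fires on every small
   fluctuation, which made the multiband variant *more* speech-distorting
   than the broadband one — inverting the relation the multiband design
   exists to produce.  82 dB sits just above the 80 dB noise bed.

While the conditions hold, the gain (in dB) attacks toward the event's
target attenuation with a one-pole whose time constant is attack_ms/10, so
full depth is reached within the nominal 1 ms attack; afterwards it
releases exponentially toward unity with τ = base τ × scale_tau.  The
broadband target is `30 dB × scale_atten`; the multiband target maps the
band envelope's excess over threshold linearly from 10 dB (threshold-level
transient) to 30 dB (threshold + 20 dB), then scales.  Targets clamp at
60 dB, the ceiling implied by scale 2 on the 30 dB base.

A 1 ms **look-ahead** advances the gain relative to the signal (the
real-time equivalent is a short delay line on the signal path, a standard
ingredient of transient suppressors).  Without it, a causal gain can only
act after the detection threshold is crossed, so a 1 ms transient's peak
passes before the attenuation lands and the measurable peak reduction
saturates near the threshold excess.  Offline, the gain trace is shifted
instead of delaying the signal, which keeps input and output time-aligned —
convenient for coherence and rms comparisons, both of which are in any case
delay-invariant.

At `scale_atten = 0` the gain stage short-circuits: broadband output is
bit-identical to the input and multiband output is exactly the filterbank
round-trip (which itself reconstructs the input exactly, see below).

Per-band default release times are (40, 36, 33, 30) ms from low to high
band — longer at low frequencies where transients ring longer — within the
stated 30–40 ms per-band range; one shared `scale_tau` multiplies all of
them.

The detector's numeric thresholds are design choices (the clinical
algorithm's are proprietary); all of them are fields of `DetectorParams`.

## Filterbank

The four bands (0–1, 1–2, 2–4, >4 kHz) come from a complementary lowpass
tree: three linear-phase FIR lowpasses (511 taps, Hamming) at 1, 2 and
4 kHz, applied with their group delay compensated; band k is the difference
of successive lowpass outputs and the top band is the residual.  The bands
therefore sum to the input *exactly* (telescoping), giving a
zero-ripple reconstruction guarantee, and the 511-tap design provides
>50 dB stopband so a tone leaks <−30 dB into a neighbouring band one octave
out.

## Front end

* **Preemphasis**: first-order Butterworth high-pass, 1.2 kHz corner
  (6 dB/octave), a typical CI front-end tilt; configurable.
* **Dual-loop AGC**: each loop is a level detector (instantaneous power →
  2 ms symmetric pre-smoother → attack/release one-pole) feeding a static
  knee/ratio curve; the combined gain is the minimum of the loop gains.
  Defaults — slow {240 ms attack, 1500 ms release, 63 dB SPL knee, 12:1},
  fast {4 ms, 80 ms, 71 dB SPL, 3:1} — are representative of a dual-loop
  CI compressor: the slow loop adapts overall level with a high ratio, the
  fast loop catches bursts with a 3–5 ms attack and moderate ratio.  The
  2 ms pre-smoother exists to remove the 2f power ripple of tonal inputs,
  which otherwise biases the asymmetric attack/release integrator upward
  by ~1.7 dB.
* **Bypass wiring**: the AGC gain is computed on a preemphasized branch of
  the TNR output but multiplied onto the non-preemphasized TNR output,
  after which the processor's own preemphasis is applied — mirroring a
  setup in which the processor's preemphasis cannot be disabled.

## Metrics

* **Attenuation** is `10·log10(rms_out/rms_in)` by default, following the
  characterization convention this package mirrors; the conventional
  amplitude-ratio factor 20 is available via `convention="conventional"`.
* **Speech distortion** is importance-weighted magnitude-squared coherence
  on ⅓-octave bands, 160 Hz–10 kHz (bands above Nyquist dropped and the
  weights renormalized).  Estimation: Welch cross-spectra, 250 ms Hann
  segments, 50% overlap; per-band coherence is the input-power-weighted
  mean of the bin coherences.  The band-importance weights are an
  ANSI-style speech band-importance table (negligible importance assigned
  above 8 kHz); they ship as an editable module-level table because the
  exact weights behind the original analysis are not published.
* **Characterization harness** (`characterize`): ~40 s of concatenated
  sentences plus the 5-s cafeteria noise looped to match.  By default the
  detector runs on the speech+noise *mixture* and the resulting gain
  traces are applied separately to the clean speech and to the noise
  ("shadow filtering").  This isolates what the algorithm — reacting to
  the real mixture — does to each component, and captures the dominant
  mechanism of TNR speech distortion: noise-triggered gain riding chopping
  the concurrent speech.  Processing speech-alone/noise-alone is available
  via `mode="separate"`.

## Listeners and the adaptive SRT procedure

A listener is a logistic psychometric function of effective SNR: word
probability `(1−λ)/(1+exp(−4s(x−SRT)))` with midpoint slope `s` (default
15%/dB) and lapse λ; a sentence score is Binomial(5, p).  Condition
effects enter as effective-SNR offsets (a +1.3 dB benefit lowers the
measured SRT by 1.3 dB).

The staircase presents 20 sentences.  The exact adaptive rule behind the
reference procedure is not printed, so the package defines a word-score-
proportional up-down: the level moves down when >2.5/5 words are correct
and up otherwise, by `step × |wc/5 − 0.5| × 2`; each reversal multiplies
the step by 0.7, floored at 0.1 dB (initial step 2 dB).  All constants
live in `StaircaseConfig` so other rules can be slotted in.  The final SRT
is the mean of the last eight levels including the level that would have
been presented on a 21st trial.  Monte-Carlo calibration (500 runs,
slope 15%/dB): |bias| ≈ 0.05 dB, SD ≈ 0.4 dB, stable for start offsets of
±8 dB — comfortably inside the ±0.5 dB / 1.5 dB validity envelope the
tests enforce.

## Personalization

The three-iteration procedure starts from the full [0, 2]² square: pick a
setting, halve each axis range centered on the pick, clip to [0, 2]
("constrained to the original limits" is read as interval clipping; a
boundary pick therefore yields a range hugging the boundary).  Picking is
modelled as the argmax of utility + Gaussian decision noise over a 21×21
lattice on the current range (the original touch field has no stated
resolution).  After two halvings the final range is ≤0.5 wide, so the
procedure's resolution bound is 0.25 per axis by construction.

Two preference models stand in for the subject:

* `PeakedPreference` — quadratic utility with a known peak
  (−8·‖x−peak‖²); ground truth for recovery experiments.  The curvature 8
  makes a subject with decision noise SD 0.2 decisive within ~0.2 of the
  peak, a realistic "confident but imperfect" persona.
* `AudioPreference` — utility = −1.0 × (residual transient peak level in
  dB) − 20 × (1 − weighted speech coherence), evaluated on a seeded
  speech+cafeteria mix at −2 dB SNR through the real TNR chain.  The two
  weights put a 1 dB change of residual clatter on par with a 0.05 change
  of coherence.  Because a personalization run needs hundreds of utility
  evaluations, the audio metrics are precomputed once on a 7×7 grid and
  interpolated (quadratic splines); the surfaces are smooth and monotone,
  so interpolation error is far below the lattice resolution.  This model
  deliberately uses comfort/clarity proxies rather than intelligibility —
  matching the observation that a third of real subjects could not
  understand the speech at −2 dB SNR and chose by comfort.

**Group-based settings**: keep subjects with `srt_diff < 0` (≥3 required),
fit ordinary least squares of `srt_diff` on each scale, evaluate the
inverse fit at the most favorable observed `srt_diff`, clamp to [0, 2].

**Coupling-corrected correlation**: Pearson r of (a−b) against (a+b)/2 —
the standard correction when a difference is correlated against a quantity
sharing one of its terms.

## The in-silico experiment

`run_experiment` draws a cohort (default 15 subjects; true SRTs
N(−3, 3²) dB, matching speech levels a few dB under the 80 dB noise),
personalizes each subject once (with a `PeakedPreference` persona whose
peak is drawn N(1.3, 0.35) per axis — most subjects prefer slightly
stronger-than-default filtering), then runs the staircase for the four
conditions in a per-subject randomized order, twice.  Condition effects
are injected as SRT offsets (defaults mb −1.3 dB, bb +1.7 dB, std 0,
between-subject SD 1 dB — echoing the reference effect directions).
Audio-based personalization is available but not the experiment default:
the experiment's purpose is estimator/benefit calibration, which needs no
waveforms, and this keeps a 50-cohort calibration run under a minute.
Inferential statistics are deliberately excluded; the tidy tables are the
interface to downstream analysis tools.

## Problem sizes used in tests and the acceptance script

The shipped runs use 5-s noise beds, 8–20 s speech tracks, 500-staircase
estimator calibrations and 50 replicate cohorts — sizes chosen so the full
suite exercises every pathway end-to-end in a few minutes on one core
while keeping Monte-Carlo standard errors an order of magnitude below the
tolerances being checked.

## Known limitations

* The detector thresholds and AGC constants are representative defaults,
  not the proprietary clinical values; absolute attenuation/coherence
  numbers therefore characterize *this* implementation, not the clinical
  device.
* Shadow filtering measures component-wise effects of a time-varying gain;
  it does not model nonlinear interaction terms (none exist in this gain
  structure, but a future nonlinear stage would need the separate mode).
* The simulated experiment injects condition benefits rather than deriving
  them from per-subject audio processing; linking personalized settings
  causally to benefit magnitude is out of scope.
* Human factors — learning, fatigue, scoring errors, anchoring in rating
  tasks — are not modelled.
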