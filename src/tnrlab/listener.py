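"""Simulated matrix-test listeners and the adaptive SRT staircase.

The speech reception threshold (SRT) is the SNR at which a listener
repeats 50% of the words of five-word matrix sentences correctly.  Human
listeners are replaced by a logistic psychometric model: the probability
of repeating one word correctly is a logistic function of the effective
SNR, centered on the listener's true SRT with a configured midpoint slope
(in percent per dB) and an optional lapse rate; a sentence score is a
binomial draw of 5 such words.

A processing condition can shift the listener's effective SNR: the
``condition_offsets`` entry for a condition is the benefit in dB added to
the presented SNR, so a +1.3 dB benefit lowers the measured SRT by 1.3 dB.

The adaptive procedure presents 20 sentences.  After each sentence the
level moves toward the 50% point by the current step scaled with how far
the word score was from 2.5/5 (full step for 0/5 or 5/5, a fifth of the
step for 2/5 or 3/5); every reversal shrinks the step by 0.7 down to a
floor of 0.1 dB.  The final SRT is the mean of the last eight levels,
including the level that would have been presented on a hypothetical 21st
trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ListenerModel",
    "StaircaseConfig",
    "StaircaseState",
    "SRTResult",
    "word_correct_prob",
    "score_sentence",
    "next_level",
    "run_staircase",
    "run_fixed_level_block",
]


@dataclass
class ListenerModel:
    """Logistic psychometric listener.

    ``srt_true_db`` is the 50% point (lapse 0); ``slope_pct_per_db`` the
    psychometric slope at that point; ``condition_offsets`` maps condition
    names to effective-SNR benefits in dB (positive = easier).
    """

    srt_true_db: float = -2.0
    slope_pct_per_db: float = 15.0
    lapse_rate: float = 0.0
    condition_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slope_pct_per_db <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse rate must be in [0, 1)")

    def effective_snr(self, snr_db: float, condition: str | None = None) -> float:
        off = self.condition_offsets.get(condition, 0.0) if condition else 0.0
        return snr_db + off


def word_correct_prob(listener: ListenerModel, snr_eff_db: float) -> float:
    """Probability of one word correct at the given effective SNR."""
    s = listener.slope_pct_per_db / 100.0
    z = 4.0 * s * (snr_eff_db - listener.srt_true_db)
    base = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return float((1.0 - listener.lapse_rate) * base)


def score_sentence(listener: ListenerModel, snr_eff_db: float,
                   rng: np.random.Generator | int | None = None,
                   n_words: int = 5) -> int:
    """Words correct out of ``n_words`` — a seeded binomial draw."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = word_correct_prob(listener, snr_eff_db)
    return int(rng.binomial(n_words, p))


@dataclass
class StaircaseConfig:
    n_trials: int = 20
    initial_step_db: float = 2.0
    step_shrink: float = 0.7
    min_step_db: float = 0.1
    n_words: int = 5
    n_final: int = 8          # trailing levels averaged into the SRT


@dataclass
class StaircaseState:
    """Trial-by-trial record of the adaptive run."""

    level_db: float
    step_db: float
    trial_index: int = 0
    direction: int = 0
    reversal_count: int = 0
    history: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.level_db):
            raise ValueError("level must be finite")


def next_level(state: StaircaseState, words_correct: int,
               cfg: StaircaseConfig | None = None) -> StaircaseState:
    """Advance the staircase by one scored trial.

    The move is downward (harder) when more than half the words were
    correct, upward otherwise, scaled by ``|wc/n - 0.5| * 2`` so scores
    near the 50% target move the level only slightly.  A direction change
    is a reversal and shrinks the step (floored at the minimum step).
    """
    cfg = cfg or StaircaseConfig()
    if not 0 <= words_correct <= cfg.n_words:
        raise ValueError("word score out of range")
    frac = words_correct / cfg.n_words
    direction = -1 if frac > 0.5 else 1
    step = state.step_db
    if state.direction != 0 and direction != state.direction:
        step = max(step * cfg.step_shrink, cfg.min_step_db)
    delta = direction * step * abs(frac - 0.5) * 2.0
    return replace(
        state,
        level_db=state.level_db + delta,
        step_db=step,
        trial_index=state.trial_index + 1,
        direction=direction,
        reversal_count=state.reversal_count
        + (1 if state.direction != 0 and direction != state.direction else 0),
        history=state.history + [(state.level_db, words_correct)],
    )


@dataclass
class SRTResult:
    """Outcome of one adaptive run.

    ``trace`` holds the 20 presented levels plus the hypothetical 21st;
    ``srt_db`` is the mean of the last ``n_final`` trace levels.
    """

    srt_db: float
    trace: tuple[float, ...]
    reversals: int
    seed: int | None = None


def srt_from_trace(trace, n_final: int = 8) -> float:
    return float(np.mean(np.asarray(trace, float)[-n_final:]))


def run_staircase(
    listener: ListenerModel,
    condition: str | None = None,
    start_level_db: float = 0.0,
    seed: int | None = None,
    cfg: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SRTResult:
    """Run one 20-sentence adaptive track and return the SRT estimate."""
    cfg = cfg or StaircaseConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    state = StaircaseState(level_db=start_level_db,
                           step_db=cfg.initial_step_db)
    for _ in range(cfg.n_trials):
        wc = score_sentence(
            listener, listener.effective_snr(state.level_db, condition),
            rng, cfg.n_words,
        )
        state = next_level(state, wc, cfg)
    trace = tuple(lv for lv, _ in state.history) + (state.level_db,)
    return SRTResult(srt_from_trace(trace, cfg.n_final), trace,
                     state.reversal_count, seed)


def run_fixed_level_block(
    listener: ListenerModel,
    condition: str | None = None,
    level_db: float = 0.0,
    n_sentences: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_words: int = 5,
) -> float:
    """Fraction of words correct over a block at one fixed level."""
    if rng is None:
        rng = np.random.default_rng(seed)
    snr_eff = listener.effective_snr(level_db, condition)
    total = sum(score_sentence(listener, snr_eff, rng, n_words)
                for _ in range(n_sentences))
    return total / (n_sentences * n_words)
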