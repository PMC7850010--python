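"""Two-down/one-up adaptive track engine.

The speech recognition threshold (SRT) is estimated with a transformed
up-down staircase: the level drops one step after two consecutive correct
responses and rises one step after any error, which converges on the
70.7%-correct point (2**-0.5) of the psychometric function.  A run collects
eight reversals; the SRT is the arithmetic mean of the last six reversal
levels.  The step size starts large and halves after the early reversals
(Levitt-style schedule); levels are clamped to configurable bounds with the
reversal logic driven by the intended direction, not the clamped position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .listener import ListenerProfile, simulate_response
from .stimuli import Condition

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "Trial",
    "RunResult",
    "step",
    "run_adaptive_track",
    "quiet_track",
    "default_masked_config",
    "default_quiet_config",
    "N_WORD_SETS",
    "WORDS_PER_SET",
]

N_WORD_SETS = 25
WORDS_PER_SET = 3


@dataclass(frozen=True)
class StaircaseConfig:
    """Rules of one adaptive track.

    Defaults follow a conventional schedule: 4-dB steps shrinking to 2 dB
    after two reversals, eight reversals total with the last six averaged.
    """

    down_count: int = 2
    up_count: int = 1
    reversals_total: int = 8
    reversals_averaged: int = 6
    initial_level: float = 0.0
    step_initial: float = 4.0
    step_final: float = 2.0
    step_change_after_reversals: int = 2
    level_bounds: tuple[float, float] = (-40.0, 20.0)
    max_trials: int = 150

    def __post_init__(self) -> None:
        if self.reversals_averaged > self.reversals_total:
            raise ValueError("cannot average more reversals than collected")
        if self.step_initial <= 0 or self.step_final <= 0:
            raise ValueError("step sizes must be positive")
        if self.level_bounds[0] >= self.level_bounds[1]:
            raise ValueError("level bounds must be ordered (min, max)")
        if self.max_trials < 20:
            raise ValueError("max_trials must be at least 20")


def default_masked_config() -> StaircaseConfig:
    """Track settings for the masked conditions (levels in dB SNR)."""
    return StaircaseConfig()


def default_quiet_config() -> StaircaseConfig:
    """Track settings for quiet runs (levels in dB re comfortable).

    Starts at -10 dB re comfortable; bounds are wide enough that tracks for
    low quiet thresholds (around -35 to -45 dB re comfortable) never clamp.
    """
    return StaircaseConfig(initial_level=-10.0, level_bounds=(-70.0, 10.0))


@dataclass
class StaircaseState:
    """Evolving state of a track: level, counters, and the reversal log."""

    current_level: float
    consecutive_correct: int = 0
    direction: str = "none"  # "down" | "up" | "none"
    reversal_levels: list[float] = field(default_factory=list)
    trial_count: int = 0
    finished: bool = False

    @classmethod
    def fresh(cls, config: StaircaseConfig) -> "StaircaseState":
        return cls(current_level=config.initial_level)


def step(
    state: StaircaseState, config: StaircaseConfig, correct: bool
) -> StaircaseState:
    """Advance the track by one response; returns a new state.

    After ``down_count`` consecutive correct responses the level moves down
    one step and the counter resets; any error moves it up.  A reversal is
    logged at the pre-move level whenever the intended direction flips.  The
    step size switches from ``step_initial`` to ``step_final`` once
    ``step_change_after_reversals`` reversals have been logged before the
    move.  The state finishes when the reversal quota or ``max_trials`` is
    reached.
    """
    if state.finished:
        raise RuntimeError("cannot step a finished staircase")

    cc = state.consecutive_correct
    move: str | None = None
    if correct:
        cc += 1
        if cc >= config.down_count:
            move = "down"
            cc = 0
    else:
        cc = 0
        move = "up"

    reversals = list(state.reversal_levels)
    direction = state.direction
    level = state.current_level
    if move is not None:
        if direction not in ("none", move):
            reversals.append(level)
        size = (
            config.step_initial
            if len(state.reversal_levels) < config.step_change_after_reversals
            else config.step_final
        )
        delta = -size if move == "down" else size
        level = float(np.clip(level + delta, *config.level_bounds))
        direction = move

    trials = state.trial_count + 1
    finished = len(reversals) >= config.reversals_total or trials >= config.max_trials
    return StaircaseState(
        current_level=level,
        consecutive_correct=cc,
        direction=direction,
        reversal_levels=reversals,
        trial_count=trials,
        finished=finished,
    )


@dataclass
class Trial:
    """One presentation: level, response, reversal flag, word metadata."""

    level_db: float
    correct: bool
    reversal: bool
    word_set: int
    word: int


@dataclass
class RunResult:
    """Outcome of one adaptive track.

    ``valid`` is true iff the full reversal quota was collected within
    ``max_trials``; a valid run's ``srt`` is the mean of the last
    ``reversals_averaged`` reversal levels.
    """

    condition: Condition
    srt: float
    reversal_levels: list[float]
    trials: list[Trial]
    valid: bool
    day: int = 0
    run_index: int = 0
    distracted: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition"] = self.condition.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunResult":
        d = dict(d)
        d["condition"] = Condition(d["condition"])
        d["trials"] = [Trial(**t) for t in d["trials"]]
        return cls(**d)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def run_adaptive_track(
    profile: ListenerProfile,
    condition: Condition,
    config: StaircaseConfig,
    rng: np.random.Generator,
    day: int = 0,
    run_index: int = 0,
) -> RunResult:
    """Run one adaptive track against a simulated listener.

    Each trial draws a word set (of 25) and a word (of 3) uniformly — the
    listener ignores word identity, so these are presentation metadata —
    then draws the 3AFC response and advances the staircase.  An aborted
    track (max_trials hit before the reversal quota) returns ``valid=False``
    with ``srt`` set to NaN.
    """
    state = StaircaseState.fresh(config)
    trials: list[Trial] = []
    while not state.finished:
        word_set = int(rng.integers(N_WORD_SETS))
        word = int(rng.integers(WORDS_PER_SET))
        correct = simulate_response(profile, condition, state.current_level, rng)
        n_rev = len(state.reversal_levels)
        nxt = step(state, config, correct)
        trials.append(
            Trial(
                level_db=state.current_level,
                correct=correct,
                reversal=len(nxt.reversal_levels) > n_rev,
                word_set=word_set,
                word=word,
            )
        )
        state = nxt

    valid = len(state.reversal_levels) >= config.reversals_total
    if valid:
        tail = state.reversal_levels[-config.reversals_averaged :]
        srt = float(np.mean(tail))
    else:
        srt = float("nan")
    return RunResult(
        condition=condition,
        srt=srt,
        reversal_levels=list(state.reversal_levels),
        trials=trials,
        valid=valid,
        day=day,
        run_index=run_index,
    )


def quiet_track(
    profile: ListenerProfile,
    config: StaircaseConfig,
    rng: np.random.Generator,
    day: int = 0,
    run_index: int = 0,
) -> RunResult:
    """Quiet-threshold run: same engine with the masker amplitude at zero.

    Levels are in dB re the comfortable reference and performance is governed
    by the listener's quiet midpoint; no masker level is ever referenced.
    """
    return run_adaptive_track(
        profile, Condition.QUIET, config, rng, day=day, run_index=run_index
    )


def runs_to_frame(runs: list[RunResult]):
    """Flatten runs to a trials table (one row per trial)."""
    import pandas as pd

    rows = []
    for r in runs:
        for i, t in enumerate(r.trials):
            rows.append(
                {
                    "day": r.day,
                    "run": r.run_index,
                    "condition": r.condition.value,
                    "trial": i,
                    "level_db": t.level_db,
                    "correct": t.correct,
                    "reversal": t.reversal,
                    "word_set": t.word_set,
                    "word": t.word,
                }
            )
    return pd.DataFrame(rows)
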