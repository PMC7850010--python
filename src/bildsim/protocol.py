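"""Multi-day remote testing protocol.

Each session (one per day, on Days 1, 2, and 7) comprises seven adaptive
runs: a single quiet run first, then three blocks of two masked runs with the
order of conditions (diotic M0T0 vs antiphasic M0Tpi) randomized within each
block.  A day's SRT per masked condition is the mean of its three valid runs,
and the day's BILD estimate is the M0T0 mean minus the M0Tpi mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .listener import ListenerProfile
from .staircase import (
    RunResult,
    StaircaseConfig,
    default_masked_config,
    default_quiet_config,
    quiet_track,
    run_adaptive_track,
)
from .stimuli import Condition

__all__ = [
    "DAYS",
    "SessionPlan",
    "SessionResult",
    "ParticipantResult",
    "ProtocolConfigs",
    "plan_session",
    "run_session",
    "run_participant",
    "results_to_frame",
]

DAYS = (1, 2, 7)
RUNS_PER_SESSION = 7
BLOCKS_PER_SESSION = 3


@dataclass(frozen=True)
class ProtocolConfigs:
    """Staircase settings for the two run families of a session."""

    masked: StaircaseConfig = field(default_factory=default_masked_config)
    quiet: StaircaseConfig = field(default_factory=default_quiet_config)


@dataclass
class SessionPlan:
    """Ordered run conditions for one day: quiet first, then 3 masked blocks."""

    day: int
    run_sequence: list[Condition]

    def __post_init__(self) -> None:
        seq = self.run_sequence
        if len(seq) != RUNS_PER_SESSION or seq[0] is not Condition.QUIET:
            raise ValueError("a session is 7 runs beginning with quiet")
        for b in range(BLOCKS_PER_SESSION):
            pair = set(seq[1 + 2 * b : 3 + 2 * b])
            if pair != {Condition.M0T0, Condition.M0TPI}:
                raise ValueError("each block must pair M0T0 with M0TPI")


def plan_session(day: int, rng: np.random.Generator) -> SessionPlan:
    """Randomize the session's run order: quiet, then 3 coin-flipped blocks."""
    if day not in DAYS:
        raise ValueError(f"day must be one of {DAYS}, got {day}")
    seq = [Condition.QUIET]
    for _ in range(BLOCKS_PER_SESSION):
        pair = [Condition.M0T0, Condition.M0TPI]
        if rng.random() < 0.5:
            pair.reverse()
        seq.extend(pair)
    return SessionPlan(day=day, run_sequence=seq)


@dataclass
class SessionResult:
    """One day's aggregates: quiet SRT, per-condition masked means, BILD.

    Per-condition means use valid runs only; if every run of a condition is
    invalid (or dropped), that day's SRT — and the BILD if either masked
    condition is affected — is NaN, emulating missing uploads.
    """

    day: int
    quiet_srt: float
    srt_m0t0: float
    srt_m0tpi: float
    bild: float
    runs: list[RunResult]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["runs"] = [r.to_dict() for r in self.runs]
        return d


def _cond_mean(runs: list[RunResult], condition: Condition) -> float:
    vals = [r.srt for r in runs if r.condition is condition and r.valid]
    return float(np.mean(vals)) if vals else float("nan")


def run_session(
    profile: ListenerProfile,
    day: int,
    configs: ProtocolConfigs,
    rng: np.random.Generator,
    drop_probability: float = 0.0,
    distraction_rate: float = 0.0,
) -> SessionResult:
    """Execute one day's seven runs and aggregate them.

    ``drop_probability`` optionally marks runs invalid at random (upload-loss
    emulation, default off); ``distraction_rate`` tags runs with a
    distraction flag that has no effect on performance.
    """
    plan = plan_session(day, rng)
    runs: list[RunResult] = []
    for idx, cond in enumerate(plan.run_sequence):
        if cond is Condition.QUIET:
            r = quiet_track(profile, configs.quiet, rng, day=day, run_index=idx)
        else:
            r = run_adaptive_track(
                profile, cond, configs.masked, rng, day=day, run_index=idx
            )
        if drop_probability > 0.0 and rng.random() < drop_probability:
            r.valid = False
            r.srt = float("nan")
        if distraction_rate > 0.0 and rng.random() < distraction_rate:
            r.distracted = True
        runs.append(r)

    srt_m0t0 = _cond_mean(runs, Condition.M0T0)
    srt_m0tpi = _cond_mean(runs, Condition.M0TPI)
    return SessionResult(
        day=day,
        quiet_srt=_cond_mean(runs, Condition.QUIET),
        srt_m0t0=srt_m0t0,
        srt_m0tpi=srt_m0tpi,
        bild=srt_m0t0 - srt_m0tpi,
        runs=runs,
    )


def run_participant(
    profile: ListenerProfile,
    configs: ProtocolConfigs | None = None,
    rng: np.random.Generator | None = None,
    days: tuple[int, ...] = DAYS,
    day_effects: dict[int, dict[str, float]] | None = None,
    drop_probability: float = 0.0,
    distraction_rate: float = 0.0,
) -> list[SessionResult]:
    """Run the full multi-day protocol for one listener.

    ``day_effects`` maps day -> per-condition threshold perturbations in dB
    (keys ``m0t0``, ``m0tpi``, ``quiet``), applied to the listener before that
    day's session; these come from the cohort variance-component model and
    generate the day-to-day (test-retest) variability.
    """
    configs = configs or ProtocolConfigs()
    rng = rng if rng is not None else np.random.default_rng()
    sessions = []
    for day in days:
        p = profile
        if day_effects and day in day_effects:
            eff = day_effects[day]
            d0 = eff.get("m0t0", 0.0)
            dpi = eff.get("m0tpi", 0.0)
            p = profile.shifted(
                mu_m0t0=d0,
                bild_true=d0 - dpi,
                mu_quiet=eff.get("quiet", 0.0),
            )
        sessions.append(
            run_session(
                p,
                day,
                configs,
                rng,
                drop_probability=drop_probability,
                distraction_rate=distraction_rate,
            )
        )
    return sessions


@dataclass
class ParticipantResult:
    """A listener's profile metadata plus their sessions."""

    participant_id: str
    age_years: float
    group: str
    sessions: list[SessionResult]

    def session_for(self, day: int) -> SessionResult | None:
        for s in self.sessions:
            if s.day == day:
                return s
        return None

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "age_years": self.age_years,
            "group": self.group,
            "sessions": [s.to_dict() for s in self.sessions],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def results_to_frame(participants: list[ParticipantResult]) -> pd.DataFrame:
    """Long-format run table: participant, age, group, day, condition, run, srt."""
    rows = []
    for p in participants:
        for s in p.sessions:
            for r in s.runs:
                rows.append(
                    {
                        "participant": p.participant_id,
                        "age": p.age_years,
                        "group": p.group,
                        "day": s.day,
                        "condition": r.condition.value,
                        "run": r.run_index,
                        "srt": r.srt,
                        "valid": r.valid,
                    }
                )
    return pd.DataFrame(rows)
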