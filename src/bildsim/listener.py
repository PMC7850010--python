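"""Simulated listeners for the 3AFC word-recognition task.

A listener is a guess-corrected logistic psychometric function per condition:

    p(correct | level) = gamma + (1 - gamma - lambda) * L((level - mu) / s)

with guess rate ``gamma = 1/3`` (three-alternative forced choice), lapse rate
``lambda``, spread ``s`` (dB), and a condition-specific midpoint ``mu``.  The
antiphasic midpoint is shifted down by the listener's true binaural
intelligibility level difference (BILD) — and, for the rare anomalous-hardware
listeners, by an additional antiphasic-only advantage.  Word identity is
ignored: only level and condition drive performance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.optimize import brentq

from .stimuli import Condition

__all__ = [
    "ListenerProfile",
    "p_correct",
    "simulate_response",
    "true_srt",
    "srt_offset",
    "TRACK_TARGET_P",
    "save_profiles",
    "load_profiles",
]

#: asymptotic proportion-correct tracked by a two-down/one-up staircase
TRACK_TARGET_P = 2.0 ** (-0.5)

GUESS_RATE_3AFC = 1.0 / 3.0


@dataclass
class ListenerProfile:
    """Psychometric parameters of one simulated participant.

    ``mu_m0t0`` and ``mu_quiet`` are psychometric midpoints in dB SNR and dB
    re comfortable respectively; ``bild_true`` shifts the antiphasic midpoint:
    ``mu_m0tpi = mu_m0t0 - bild_true - hardware_anomaly_db``.
    ``hardware_anomaly_db`` models the outlier households whose personal
    headphones produced a grossly inflated antiphasic advantage.
    """

    age_years: float
    group: str  # "child" | "adult"
    mu_m0t0: float
    bild_true: float
    mu_quiet: float
    slope: float = 2.0
    guess_rate: float = GUESS_RATE_3AFC
    lapse_rate: float = 0.02
    hardware_anomaly_db: float = 0.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("child", "adult"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if abs(self.guess_rate - GUESS_RATE_3AFC) > 1e-12:
            raise ValueError("guess_rate is fixed at 1/3 for the 3AFC task")
        if not math.isfinite(self.bild_true):
            raise ValueError("bild_true must be finite")
        if self.hardware_anomaly_db < 0:
            raise ValueError("hardware_anomaly_db must be >= 0")

    def midpoint(self, condition: Condition) -> float:
        if condition is Condition.QUIET:
            return self.mu_quiet
        if condition is Condition.M0T0:
            return self.mu_m0t0
        if condition is Condition.M0TPI:
            return self.mu_m0t0 - self.bild_true - self.hardware_anomaly_db
        raise ValueError(f"unknown condition {condition!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ListenerProfile":
        return cls(**d)

    def shifted(self, **deltas: float) -> "ListenerProfile":
        """Copy with additive shifts to midpoint fields (day perturbations)."""
        kw = {}
        for name, dv in deltas.items():
            kw[name] = getattr(self, name) + dv
        return replace(self, **kw)


def p_correct(profile: ListenerProfile, condition: Condition, level: float) -> float:
    """Probability of a correct 3AFC response at the given level (dB)."""
    if not math.isfinite(level):
        raise ValueError("level must be finite")
    mu = profile.midpoint(condition)
    x = (level - mu) / profile.slope
    # numerically safe logistic
    if x >= 0:
        logistic = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        logistic = e / (1.0 + e)
    g, lam = profile.guess_rate, profile.lapse_rate
    return g + (1.0 - g - lam) * logistic


def simulate_response(
    profile: ListenerProfile,
    condition: Condition,
    level: float,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli 3AFC response; reproducible under a fixed stream state."""
    return rng.random() < p_correct(profile, condition, level)


def srt_offset(
    slope: float,
    lapse_rate: float,
    guess_rate: float = GUESS_RATE_3AFC,
    target_p: float = TRACK_TARGET_P,
) -> float:
    """Closed-form offset from the psychometric midpoint to the tracked point.

    The two-down/one-up rule converges to ``p = 2**-0.5``; the level attaining
    it is ``mu + slope * logit((p - gamma) / (1 - gamma - lambda))``.
    """
    q = (target_p - guess_rate) / (1.0 - guess_rate - lapse_rate)
    if not 0.0 < q < 1.0:
        raise ValueError("target proportion not reachable with this lapse rate")
    return slope * math.log(q / (1.0 - q))


def true_srt(profile: ListenerProfile, condition: Condition) -> float:
    """Level at which p_correct equals 2**-0.5, by root-finding.

    This is the asymptotic convergence point of the two-down/one-up track and
    serves as the recovery target for staircase simulations.  Raises if the
    lapse rate makes the tracked proportion unreachable.
    """
    if 1.0 - profile.lapse_rate <= TRACK_TARGET_P:
        raise ValueError("lapse rate too high: 2**-0.5 is not reachable")
    mu = profile.midpoint(condition)
    half_width = 60.0 * profile.slope + 1.0
    return brentq(
        lambda lv: p_correct(profile, condition, lv) - TRACK_TARGET_P,
        mu - half_width,
        mu + half_width,
        xtol=1e-10,
    )


def save_profiles(profiles: list[ListenerProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=1)


def load_profiles(path) -> list[ListenerProfile]:
    with open(path) as fh:
        return [ListenerProfile.from_dict(d) for d in json.load(fh)]
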