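"""End-to-end study driver: cohort sampling through sessions to the report."""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, sample_cohort, sample_day_effects
from .protocol import ParticipantResult, ProtocolConfigs, run_participant

__all__ = ["simulate_study"]


def simulate_study(
    config: CohortConfig,
    rng: np.random.Generator,
    days: tuple[int, ...] = (1, 2, 7),
    configs: ProtocolConfigs | None = None,
    drop_probability: float = 0.0,
) -> list[ParticipantResult]:
    """Simulate the whole remote study once.

    Samples a cohort from the population model, draws each listener's
    per-day threshold perturbations, and runs the full session protocol
    (quiet run plus three randomized masked blocks per day) through the
    adaptive staircase engine for every listener.
    """
    configs = configs or ProtocolConfigs()
    profiles = sample_cohort(config, rng)
    effects = sample_day_effects(config, profiles, rng, days=days)
    out = []
    for prof in profiles:
        sessions = run_participant(
            prof,
            configs=configs,
            rng=rng,
            days=days,
            day_effects=effects[prof.participant_id],
            drop_probability=drop_probability,
        )
        out.append(
            ParticipantResult(
                participant_id=prof.participant_id,
                age_years=prof.age_years,
                group=prof.group,
                sessions=sessions,
            )
        )
    return out
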