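"""Population model: sampling simulated cohorts and reliability structures.

Listeners are drawn from an additive variance-component model.  A child's
true diotic (M0T0) SRT is the group mean plus an age trend plus a
between-subject effect; the true BILD is Normal, so the antiphasic threshold
is the diotic one minus the BILD; quiet thresholds are modeled analogously.
Day-to-day test-retest variability enters as independent per-day, per-
condition perturbations whose standard deviations set the population
intraclass correlation (ICC):

    ICC = sigma_between^2 / (sigma_between^2 + sigma_day^2)

Named presets calibrate the group means to the published Day-1 remote values
and the variance components to the published test-retest ICCs, so a simulated
study reproduces the reported group structure.  Group means are specified as
*true SRTs at the staircase's 70.7% convergence point*; sampling converts
them to psychometric midpoints internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .listener import ListenerProfile, srt_offset

__all__ = [
    "CohortConfig",
    "DayEffect",
    "ReliabilityComponents",
    "sample_cohort",
    "sample_day_effects",
    "preset_paper_day1",
    "preset_reliability",
    "generate_srt_matrix",
    "RELIABILITY_ICC",
]

#: published Day-1 group mean SRTs (dB SNR; quiet in dB re comfortable)
DAY1_MEANS = {
    "child": {"m0t0": -8.9, "m0tpi": -15.0, "quiet": -35.1},
    "adult": {"m0t0": -11.3, "m0tpi": -17.1, "quiet": -42.1},
}

#: published test-retest ICC point estimates per (measure, day-pair)
RELIABILITY_ICC = {
    "m0t0-day12": 0.85,
    "m0t0-day17": 0.47,
    "m0tpi-day12": 0.93,
    "m0tpi-day17": 0.83,
    "bild-day12": 0.89,
    "bild-day17": 0.76,
    "quiet-day12": 0.57,
    "quiet-day17": 0.46,
}


@dataclass
class CohortConfig:
    """Generative parameters of a simulated study population.

    ``mean_true_srt`` maps group -> condition -> true SRT at the 70.7% point.
    ``between_subject_sd`` is the masked between-subject spread applied to the
    diotic threshold; the antiphasic spread emerges from it plus ``bild_sd``.
    ``day_sd`` / ``day7_sd`` map condition -> SD of the day perturbation for
    the short (Day 1/2) and long (Day 7) retest intervals.  ``age_slope`` is
    the child threshold improvement in dB per year, centered on the midpoint
    of the child age range.  With probability ``outlier_rate`` a listener
    gets an anomalous-hardware antiphasic advantage drawn uniformly from
    ``outlier_advantage_range``.
    """

    n_children: int = 28
    n_adults: int = 11
    child_age_range: tuple[float, float] = (6.7, 17.6)
    adult_age_range: tuple[float, float] = (22.8, 45.8)
    mean_true_srt: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DAY1_MEANS.items()}
    )
    between_subject_sd: float = 2.5
    bild_sd: float = 2.0
    quiet_between_sd: float = 8.0
    day_sd: dict = field(default_factory=dict)
    day7_sd: dict = field(default_factory=dict)
    age_slope: float = -0.55
    quiet_age_slope: float = -0.55
    outlier_rate: float = 0.0
    outlier_advantage_range: tuple[float, float] = (7.1, 9.6)
    slope: float = 2.0
    lapse_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_children < 0 or self.n_adults < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")
        for sd in (self.between_subject_sd, self.bild_sd, self.quiet_between_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        if not self.day_sd:
            self.day_sd = self._default_day_sd(day7=False)
        if not self.day7_sd:
            self.day7_sd = self._default_day_sd(day7=True)

    def _between_sd(self, measure: str) -> float:
        if measure == "m0t0":
            return self.between_subject_sd
        if measure == "m0tpi":
            return float(np.hypot(self.between_subject_sd, self.bild_sd))
        if measure == "bild":
            return self.bild_sd
        if measure == "quiet":
            return self.quiet_between_sd
        raise ValueError(f"unknown measure {measure!r}")

    def _default_day_sd(self, day7: bool) -> dict:
        """Day-perturbation SDs reproducing the published ICC structure.

        Day 1 and Day 2 share the short-interval SD from the Day1-Day2 ICC.
        The Day-7 SD is solved from the Day1-Day7 ICC treating the pairwise
        consistency correlation as sigma_b^2 / sqrt((sigma_b^2 + sd2^2) *
        (sigma_b^2 + sd7^2)) with unequal day variances.
        """
        out = {}
        for measure in ("m0t0", "m0tpi", "quiet"):
            sb2 = self._between_sd(measure) ** 2
            if sb2 == 0.0:  # degenerate population: no day scatter either
                out[measure] = 0.0
                continue
            icc12 = RELIABILITY_ICC[f"{measure}-day12"]
            sd2_sq = sb2 * (1.0 - icc12) / icc12
            if not day7:
                out[measure] = float(np.sqrt(sd2_sq))
            else:
                icc17 = RELIABILITY_ICC[f"{measure}-day17"]
                sd7_sq = (sb2 / icc17) ** 2 / (sb2 + sd2_sq) - sb2
                out[measure] = float(np.sqrt(max(sd7_sq, 0.0)))
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("child_age_range", "adult_age_range", "outlier_advantage_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yml", ".yaml")):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CohortConfig":
        path = str(path)
        with open(path) as fh:
            if path.endswith((".yml", ".yaml")):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class DayEffect:
    """Per-day threshold perturbation of one participant (dB per condition)."""

    participant_id: str
    day: int
    delta: dict


def preset_paper_day1() -> CohortConfig:
    """Cohort calibrated to the published Day-1 remote group values.

    28 children (6.7-17.6 y) and 11 adults (22.8-45.8 y); group mean true
    SRTs set to the published Day-1 means per condition; no anomalous-
    hardware outliers; variance components at the documented defaults.
    """
    return CohortConfig(outlier_rate=0.0)


@dataclass(frozen=True)
class ReliabilityComponents:
    """Variance components whose ICC ratio equals a published point estimate."""

    between_subject_sd: float
    day_sd: float
    icc: float

    @property
    def population_icc(self) -> float:
        b2 = self.between_subject_sd**2
        return b2 / (b2 + self.day_sd**2)


def preset_reliability(condition_pair: str) -> ReliabilityComponents:
    """Variance components for one (measure, day-pair) reliability target.

    ``condition_pair`` is e.g. ``"m0t0-day12"`` or ``"bild-day17"``.  The
    between-subject SD comes from the cohort defaults for that measure and
    the day SD is solved so that sigma_b^2/(sigma_b^2 + sigma_d^2) equals the
    published ICC exactly; both columns of a generated matrix share the day
    SD (exchangeable-days model), which is what the direct-matrix reliability
    recovery uses.
    """
    if condition_pair not in RELIABILITY_ICC:
        raise ValueError(
            f"unknown pair {condition_pair!r}; choose from {sorted(RELIABILITY_ICC)}"
        )
    icc = RELIABILITY_ICC[condition_pair]
    measure = condition_pair.split("-")[0]
    between = CohortConfig()._between_sd(measure)
    day_sd = between * float(np.sqrt((1.0 - icc) / icc))
    return ReliabilityComponents(between_subject_sd=between, day_sd=day_sd, icc=icc)


def generate_srt_matrix(
    components: ReliabilityComponents,
    n_subjects: int,
    k_measurements: int,
    rng: np.random.Generator,
    mean: float = 0.0,
) -> np.ndarray:
    """Draw an n x k SRT matrix from the additive two-way model.

    Cell (i, j) = mean + subject_i + noise_ij with subject SD
    ``between_subject_sd`` and cell SD ``day_sd``; its population consistency
    ICC is ``components.population_icc``.
    """
    subj = rng.normal(0.0, components.between_subject_sd, size=(n_subjects, 1))
    noise = rng.normal(0.0, components.day_sd, size=(n_subjects, k_measurements))
    return mean + subj + noise


def _sample_group(
    config: CohortConfig,
    group: str,
    n: int,
    age_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[ListenerProfile]:
    means = config.mean_true_srt[group]
    offset = srt_offset(config.slope, config.lapse_rate)
    age_mid = 0.5 * (age_range[0] + age_range[1])
    profiles = []
    for i in range(n):
        age = float(rng.uniform(*age_range))
        age_term = config.age_slope * (age - age_mid) if group == "child" else 0.0
        q_age_term = (
            config.quiet_age_slope * (age - age_mid) if group == "child" else 0.0
        )
        true_m0t0 = (
            means["m0t0"] + age_term + rng.normal(0.0, config.between_subject_sd)
        )
        bild_mean = means["m0t0"] - means["m0tpi"]
        bild_true = float(rng.normal(bild_mean, config.bild_sd))
        true_quiet = (
            means["quiet"] + q_age_term + rng.normal(0.0, config.quiet_between_sd)
        )
        anomaly = 0.0
        if config.outlier_rate > 0.0 and rng.random() < config.outlier_rate:
            anomaly = float(rng.uniform(*config.outlier_advantage_range))
        profiles.append(
            ListenerProfile(
                age_years=age,
                group=group,
                mu_m0t0=true_m0t0 - offset,
                bild_true=bild_true,
                mu_quiet=true_quiet - offset,
                slope=config.slope,
                lapse_rate=config.lapse_rate,
                hardware_anomaly_db=anomaly,
                participant_id=f"{group[0]}{i:03d}",
            )
        )
    return profiles


def sample_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[ListenerProfile]:
    """Sample a full cohort of listener profiles from the population model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    children = _sample_group(config, "child", config.n_children, config.child_age_range, rng)
    adults = _sample_group(config, "adult", config.n_adults, config.adult_age_range, rng)
    return children + adults


def sample_day_effects(
    config: CohortConfig,
    profiles: list[ListenerProfile],
    rng: np.random.Generator,
    days: tuple[int, ...] = (1, 2, 7),
) -> dict[str, dict[int, dict[str, float]]]:
    """Draw independent per-day threshold perturbations for every listener.

    Returns participant_id -> day -> {condition: delta dB}.  Days 1 and 2 use
    the short-interval SDs, Day 7 the long-interval SDs; all deltas are
    zero-mean (no drift in group means over sessions).
    """
    effects: dict[str, dict[int, dict[str, float]]] = {}
    for p in profiles:
        per_day = {}
        for day in days:
            sds = config.day7_sd if day == 7 else config.day_sd
            per_day[day] = {
                cond: float(rng.normal(0.0, sds[cond]))
                for cond in ("m0t0", "m0tpi", "quiet")
            }
        effects[p.participant_id] = per_day
    return effects
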