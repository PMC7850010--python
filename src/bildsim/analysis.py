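"""Statistical stage: group summaries, reliability, screening checks.

Implements the analyses the remote-assessment protocol reports: two-way
consistency intraclass correlation (ICC) with its exact F-based 95% CI,
one-tailed Pearson and Welch tests for age effects, ordinary-least-squares
prediction bands for screening remote data against laboratory norms, and the
audibility margin check comparing each listener's quiet SRT with their
lowest masked SRT.

The ICC here is the single-measure two-way consistency coefficient ICC(C,1),
computed from the two-way ANOVA mean squares without interaction:

    ICC = (MS_rows - MS_err) / (MS_rows + (k - 1) * MS_err)

with the confidence interval from the F-ratio MS_rows/MS_err on (n-1) and
(n-1)(k-1) degrees of freedom.  Qualitative labels follow the convention
"good" for 0.75-0.90 and "excellent" above 0.90.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .protocol import ParticipantResult
from .stimuli import Condition

__all__ = [
    "IccResult",
    "PredictionBand",
    "OutlierFlag",
    "AudibilityResult",
    "AnalysisReport",
    "icc_consistency",
    "icc_label",
    "pearson_one_tailed",
    "welch_one_tailed",
    "fit_prediction_band",
    "flag_outliers",
    "audibility_check",
    "build_report",
]

AUDIBILITY_MARGIN_DB = 6.0


@dataclass
class IccResult:
    """Single-measure two-way consistency ICC with its confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_measurements: int
    model: str = "two-way consistency, single measure"

    def __post_init__(self) -> None:
        if self.n_subjects < 3 or self.k_measurements < 2:
            raise ValueError("ICC needs n >= 3 subjects and k >= 2 measurements")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")

    @property
    def label(self) -> str:
        return icc_label(self.estimate)


def icc_label(estimate: float) -> str:
    """Qualitative reliability band for an ICC point estimate."""
    if estimate > 0.90:
        return "excellent"
    if estimate >= 0.75:
        return "good"
    if estimate >= 0.5:
        return "moderate"
    return "poor"


def icc_consistency(matrix: np.ndarray, alpha: float = 0.05) -> IccResult:
    """Two-way consistency ICC (single measure) from an n x k matrix.

    Rows are subjects, columns repeated measurements (days).  Rows containing
    missing values are listwise-deleted first.  Raises on fewer than 3
    complete rows or zero total variance.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be n x k with k >= 2")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 complete subjects")

    grand = m.mean()
    if np.allclose(m, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols

    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = max(ss_err / df_err, 0.0)

    if ms_rows + (k - 1) * ms_err == 0:
        raise ValueError("degenerate mean squares: ICC undefined")
    estimate = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    # exact F-based interval for ICC(C,1)
    if ms_err == 0.0:
        lo = hi = 1.0
    else:
        f_obs = ms_rows / ms_err
        f_hi = _stats.f.ppf(1.0 - alpha / 2.0, df_rows, df_err)
        f_lo_q = _stats.f.ppf(1.0 - alpha / 2.0, df_err, df_rows)
        fl = f_obs / f_hi
        fu = f_obs * f_lo_q
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
    return IccResult(
        estimate=float(estimate),
        ci_low=float(min(lo, estimate)),
        ci_high=float(max(hi, estimate)),
        n_subjects=n,
        k_measurements=k,
    )


def pearson_one_tailed(
    x: np.ndarray, y: np.ndarray, direction: str
) -> tuple[float, float]:
    """Pearson r with a one-tailed p in the stated direction.

    p comes from the t transform t = r * sqrt((n-2) / (1 - r^2)) on n-2
    degrees of freedom; ``direction`` is "positive" or "negative".
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt(float(np.sum(sx**2)) * float(np.sum(sy**2)))
    if denom == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.sum(sx * sy)) / denom
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(_stats.t.sf(t, n - 2))  # P(T > t): positive direction
        if direction == "negative":
            p = 1.0 - p
    return r, p


def welch_one_tailed(
    a: np.ndarray, b: np.ndarray, direction: str
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, one tailed; returns (t, df, p).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom.  ``direction`` "positive" tests
    mean_a > mean_b; "negative" tests mean_a < mean_b.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va = float(np.var(a, ddof=1)) / a.size
    vb = float(np.var(b, ddof=1)) / b.size
    se2 = va + vb
    if se2 == 0.0:
        if a.mean() == b.mean():
            raise ValueError("degenerate samples: zero variance and equal means")
        t = math.inf if a.mean() > b.mean() else -math.inf
        df = float(a.size + b.size - 2)
    else:
        t = (float(a.mean()) - float(b.mean())) / math.sqrt(se2)
        df = se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = float(_stats.t.sf(t, df))
    if direction == "negative":
        p = 1.0 - p
    return t, float(df), p


@dataclass
class PredictionBand:
    """OLS line fit with its prediction interval for a new observation.

    The band at x0 is yhat(x0) +/- t_{1-(1-level)/2, n-2} * s *
    sqrt(1 + 1/n + (x0 - mean_x)^2 / sxx).
    """

    slope: float
    intercept: float
    residual_sd: float
    n: int
    mean_x: float
    sxx: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("prediction band needs n >= 3")
        if self.sxx <= 0:
            raise ValueError("degenerate design: sxx must be positive")

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)

    def half_width(self, x0):
        x0 = np.asarray(x0, dtype=float)
        tcrit = _stats.t.ppf(1.0 - (1.0 - self.level) / 2.0, self.n - 2)
        return (
            tcrit
            * self.residual_sd
            * np.sqrt(1.0 + 1.0 / self.n + (x0 - self.mean_x) ** 2 / self.sxx)
        )

    def lower(self, x0):
        return self.predict(x0) - self.half_width(x0)

    def upper(self, x0):
        return self.predict(x0) + self.half_width(x0)


def fit_prediction_band(
    ages: np.ndarray, srts: np.ndarray, level: float = 0.95
) -> PredictionBand:
    """OLS fit of SRT on age with the prediction interval at ``level``."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(srts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (age, srt) pairs")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("ages are collinear/degenerate")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return PredictionBand(
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        n=int(x.size),
        mean_x=float(x.mean()),
        sxx=sxx,
        level=level,
    )


@dataclass
class OutlierFlag:
    """A point outside the prediction band, with the side it fell on."""

    index: int
    age: float
    value: float
    side: str  # "below" | "above"


def flag_outliers(
    band: PredictionBand, observations: list[tuple[float, float]]
) -> list[OutlierFlag]:
    """Flag (age, srt) points falling outside the prediction band."""
    flags = []
    for i, (age, val) in enumerate(observations):
        lo = float(band.lower(age))
        hi = float(band.upper(age))
        if val < lo:
            flags.append(OutlierFlag(index=i, age=age, value=val, side="below"))
        elif val > hi:
            flags.append(OutlierFlag(index=i, age=age, value=val, side="above"))
    return flags


@dataclass
class AudibilityResult:
    """Audibility margin of one dataset (listener x day).

    ``margin`` is the lowest masked target level (converted to dB re the
    comfortable reference via the masker reference level) minus the quiet
    SRT; a dataset is flagged when the margin is strictly below 6 dB,
    indicating masked recognition could have been audibility-limited.
    """

    margin: float | None
    flagged: bool | None


def audibility_check(
    quiet_srt: float,
    masked_srts: list[float],
    masker_ref: float = 0.0,
) -> AudibilityResult:
    """Compare the quiet SRT against the minimum masked SRT.

    Masked SRTs (dB SNR) are converted to target levels re the comfortable
    reference as ``masker_ref + srt``; the default reference of 0 dB places
    the masker at the comfortable level.  A missing quiet SRT yields a
    missing flag.
    """
    masked = [m for m in masked_srts if not math.isnan(m)]
    if not masked:
        raise ValueError("need at least one masked SRT")
    if quiet_srt is None or math.isnan(quiet_srt):
        return AudibilityResult(margin=None, flagged=None)
    margin = masker_ref + min(masked) - quiet_srt
    return AudibilityResult(margin=margin, flagged=margin < AUDIBILITY_MARGIN_DB)


@dataclass
class AnalysisReport:
    """Assembled group statistics of a simulated (or loaded) study."""

    group_means: dict = field(default_factory=dict)
    icc: dict = field(default_factory=dict)
    age_correlations: dict = field(default_factory=dict)
    group_tests: dict = field(default_factory=dict)
    audibility_flags: list = field(default_factory=list)
    outlier_flags: dict = field(default_factory=dict)
    n_participants: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if hasattr(obj, "__dataclass_fields__"):
                return _clean(asdict(obj))
            if isinstance(obj, float) and math.isnan(obj):
                return None
            return obj

        with open(path, "w") as fh:
            json.dump(_clean(asdict(self)), fh, indent=1)

    def summary_text(self) -> str:
        lines = ["Group mean SRTs (per day):"]
        for key, val in sorted(self.group_means.items()):
            lines.append(f"  {key}: {val:+.2f} dB")
        lines.append("Test-retest ICC:")
        for key, r in sorted(self.icc.items()):
            if r is None:
                lines.append(f"  {key}: unavailable")
            else:
                lines.append(
                    f"  {key}: {r.estimate:.2f} "
                    f"(CI {r.ci_low:.2f}-{r.ci_high:.2f}, {r.label})"
                )
        n_flagged = sum(1 for f in self.audibility_flags if f[2])
        lines.append(f"Audibility-limited datasets: {n_flagged}")
        return "\n".join(lines)


_MEASURES = {
    "m0t0": lambda s: s.srt_m0t0,
    "m0tpi": lambda s: s.srt_m0tpi,
    "bild": lambda s: s.bild,
    "quiet": lambda s: s.quiet_srt,
}


def _measure_matrix(
    participants: list[ParticipantResult], measure: str, days: tuple[int, int]
) -> np.ndarray:
    getter = _MEASURES[measure]
    rows = []
    for p in participants:
        row = []
        for day in days:
            s = p.session_for(day)
            row.append(getter(s) if s is not None else float("nan"))
        rows.append(row)
    return np.array(rows, dtype=float)


def build_report(
    participants: list[ParticipantResult],
    lab_participants: list[ParticipantResult] | None = None,
    masker_ref: float = 0.0,
) -> AnalysisReport:
    """Assemble the full statistical report for a study's results.

    Computes group x condition x day means, per-group BILD means, test-retest
    ICCs per measure for the Day 1-2 and Day 1-7 pairs (listwise deletion per
    pair; unavailable when fewer than 3 complete participants), one-tailed
    age correlations and child-vs-adult Welch tests on Day-1 data, and
    audibility flags for every listener x day dataset.  When laboratory-mode
    results are supplied, their child Day-1 data define 95% prediction bands
    per measure and remote child Day-1 values are screened against them.
    """
    if not participants or not any(p.sessions for p in participants):
        raise ValueError("need at least one participant with a session")

    report = AnalysisReport()
    days_present = sorted({s.day for p in participants for s in p.sessions})
    groups = ("child", "adult")
    report.n_participants = {
        g: sum(1 for p in participants if p.group == g) for g in groups
    }

    for g in groups:
        for day in days_present:
            vals = {m: [] for m in _MEASURES}
            for p in participants:
                if p.group != g:
                    continue
                s = p.session_for(day)
                if s is None:
                    continue
                for m, getter in _MEASURES.items():
                    v = getter(s)
                    if not math.isnan(v):
                        vals[m].append(v)
            for m, vlist in vals.items():
                if vlist:
                    report.group_means[f"{g}/{m}/day{day}"] = float(np.mean(vlist))

    for measure in _MEASURES:
        for pair, tag in (((1, 2), "day12"), ((1, 7), "day17")):
            if not set(pair) <= set(days_present):
                continue
            mat = _measure_matrix(participants, measure, pair)
            try:
                report.icc[f"{measure}-{tag}"] = icc_consistency(mat)
            except ValueError:
                report.icc[f"{measure}-{tag}"] = None

    # Day-1 age effects among children (directional: thresholds fall with age)
    child_day1 = [
        (p.age_years, p.session_for(1))
        for p in participants
        if p.group == "child" and p.session_for(1) is not None
    ]
    for measure, getter in _MEASURES.items():
        pairs = [
            (age, getter(s)) for age, s in child_day1 if not math.isnan(getter(s))
        ]
        if len(pairs) >= 3:
            ages, vals = zip(*pairs)
            try:
                r, p_val = pearson_one_tailed(ages, vals, direction="negative")
                report.age_correlations[f"child/{measure}/day1"] = {"r": r, "p": p_val}
            except ValueError:
                pass

    # Day-1 group differences (directional: children poorer, i.e. higher SRT)
    for measure, getter in _MEASURES.items():
        by_group = {g: [] for g in groups}
        for p in participants:
            s = p.session_for(1)
            if s is None:
                continue
            v = getter(s)
            if not math.isnan(v):
                by_group[p.group].append(v)
        if len(by_group["child"]) >= 2 and len(by_group["adult"]) >= 2:
            direction = "positive" if measure != "bild" else "negative"
            try:
                t, df, p_val = welch_one_tailed(
                    by_group["child"], by_group["adult"], direction=direction
                )
                report.group_tests[f"child_vs_adult/{measure}/day1"] = {
                    "t": t,
                    "df": df,
                    "p": p_val,
                }
            except ValueError:
                pass

    for p in participants:
        for s in p.sessions:
            masked = [s.srt_m0t0, s.srt_m0tpi]
            if all(math.isnan(v) for v in masked):
                continue
            res = audibility_check(s.quiet_srt, masked, masker_ref=masker_ref)
            report.audibility_flags.append(
                (p.participant_id, s.day, res.flagged, res.margin)
            )

    if lab_participants:
        for measure, getter in _MEASURES.items():
            if measure == "quiet":
                continue
            lab_pairs = [
                (p.age_years, getter(p.session_for(1)))
                for p in lab_participants
                if p.group == "child" and p.session_for(1) is not None
            ]
            lab_pairs = [(a, v) for a, v in lab_pairs if not math.isnan(v)]
            if len(lab_pairs) < 3:
                continue
            ages, vals = zip(*lab_pairs)
            band = fit_prediction_band(np.array(ages), np.array(vals))
            remote_pairs = [
                (p.age_years, getter(p.session_for(1)), p.participant_id)
                for p in participants
                if p.group == "child" and p.session_for(1) is not None
            ]
            remote_pairs = [t for t in remote_pairs if not math.isnan(t[1])]
            flags = flag_outliers(band, [(a, v) for a, v, _ in remote_pairs])
            report.outlier_flags[measure] = [
                (remote_pairs[f.index][2], f.side, f.value) for f in flags
            ]
    return report
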