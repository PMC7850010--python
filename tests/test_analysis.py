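"""Statistical kernels: ICC, one-tailed tests, prediction bands, screening."""

import math

import numpy as np
import pytest
from scipy import stats as sp_stats

from bildsim import (
    audibility_check,
    build_report,
    fit_prediction_band,
    flag_outliers,
    icc_consistency,
    pearson_one_tailed,
    preset_paper_day1,
    simulate_study,
    welch_one_tailed,
)
from bildsim.analysis import icc_label


def icc_anova_oracle(m):
    """Brute-force two-way ANOVA mean squares, written independently."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    msr = k * sum((m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIccConsistency:
    def test_identical_columns_give_one(self):
        m = np.column_stack([np.arange(6.0), np.arange(6.0)])
        res = icc_consistency(m)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_high == 1.0

    def test_constant_column_offset_is_removed(self, rng):
        base = rng.normal(size=(10, 2))
        shifted = base.copy()
        shifted[:, 1] += 7.5
        assert icc_consistency(shifted).estimate == pytest.approx(
            icc_consistency(base).estimate, abs=1e-12
        )

    def test_affine_rescaling_invariance(self, rng):
        m = rng.normal(size=(12, 2))
        a = icc_consistency(m).estimate
        b = icc_consistency(3.0 * m - 40.0).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_six_by_two_matrix_matches_anova_oracle(self):
        rows = np.array([0.0, 2, 4, 6, 8, 10])
        noise = np.array([1.0, -1, 1, -1, 1, -1])
        m = np.column_stack([rows, rows + noise])
        assert icc_consistency(m).estimate == pytest.approx(
            icc_anova_oracle(m), abs=1e-10
        )

    def test_random_matrices_match_oracle_to_1e10(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            k = int(rng.integers(2, 5))
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert icc_consistency(m).estimate == pytest.approx(
                icc_anova_oracle(m), abs=1e-10
            )

    def test_ci_brackets_estimate_and_has_coverage_shape(self, rng):
        m = rng.normal(size=(20, 2)) + 2.0 * rng.normal(size=(20, 1))
        res = icc_consistency(m)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert res.n_subjects == 20 and res.k_measurements == 2

    def test_listwise_deletion_of_missing_rows(self, rng):
        m = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
        m_missing = np.vstack([m, [[np.nan, 1.0]]])
        assert icc_consistency(m_missing).estimate == pytest.approx(
            icc_consistency(m).estimate
        )
        assert icc_consistency(m_missing).n_subjects == 10

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_consistency(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            icc_consistency(np.random.default_rng(0).normal(size=(2, 2)))

    def test_qualitative_labels(self):
        assert icc_label(0.95) == "excellent"
        assert icc_label(0.85) == "good"
        assert icc_label(0.6) == "moderate"


class TestPearsonOneTailed:
    def test_perfect_line_gives_r_one(self):
        x = np.arange(10.0)
        r, p = pearson_one_tailed(x, 2 * x + 1, "positive")
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_zero_correlation_gives_half(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, -1, -1, 1])
        r, p = pearson_one_tailed(x, y, "negative")
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_t_distribution_oracle_n30(self):
        # r = -0.32 at n = 30: one-tailed (negative) p ~ 0.042
        r = -0.32
        t = r * math.sqrt(28 / (1 - r**2))
        p_oracle = sp_stats.t.cdf(t, 28)
        assert p_oracle == pytest.approx(0.042, abs=5e-4)
        # construct data with that exact r and check our p
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            r_i, p_i = pearson_one_tailed(x, y, "negative")
            t_i = r_i * math.sqrt(28 / (1 - r_i**2))
            assert p_i == pytest.approx(sp_stats.t.cdf(t_i, 28), abs=1e-10)

    def test_matches_scipy_one_sided(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        for direction, alt in (("positive", "greater"), ("negative", "less")):
            r, p = pearson_one_tailed(x, y, direction)
            r_sp, p_sp = sp_stats.pearsonr(x, y, alternative=alt)
            assert r == pytest.approx(r_sp, abs=1e-10)
            assert p == pytest.approx(p_sp, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_one_tailed([1.0, 1, 1], [1.0, 2, 3], "positive")


class TestWelchOneTailed:
    def test_identical_samples_give_half(self):
        t, df, p = welch_one_tailed([1.0, 2, 3], [1.0, 2, 3], "positive")
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_large_separation_gives_extreme_p(self):
        a = np.array([1.0, 2, 3])
        b = a + 10.0
        t, df, p = welch_one_tailed(a, b, "positive")
        assert t < -5 and p > 0.999
        _, _, p_neg = welch_one_tailed(a, b, "negative")
        assert p_neg < 1e-3

    def test_hand_computed_oracle(self):
        a = np.array([0.0, 1, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5, 6])
        t, df, p = welch_one_tailed(a, b, "negative")
        # closed form: means 2 and 4, s^2 = 2.5 each, se = 1, t = -2, df = 8
        assert t == pytest.approx(-2.0, abs=1e-12)
        assert df == pytest.approx(8.0, abs=1e-12)
        assert p == pytest.approx(sp_stats.t.cdf(-2.0, 8), abs=1e-10)

    def test_matches_scipy(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(0.8, 2.0, size=14)
        t, df, p = welch_one_tailed(a, b, "positive")
        ref = sp_stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_one_tailed([1.0, 1.0], [1.0, 1.0], "positive")


class TestPredictionBand:
    def test_noiseless_line_collapses_band(self):
        x = np.arange(6.0, 18.0)
        band = fit_prediction_band(x, -0.5 * x - 4.0)
        assert band.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert float(band.half_width(10.0)) == pytest.approx(0.0, abs=1e-8)

    def test_band_narrowest_at_mean_age(self, rng):
        x = np.linspace(6, 17, 15)
        y = -0.5 * x + rng.normal(0, 2, size=15)
        band = fit_prediction_band(x, y)
        widths = band.half_width(np.array([6.0, band.mean_x, 17.0]))
        assert widths[1] < widths[0] and widths[1] < widths[2]

    def test_closed_form_oracle_at_two_ages(self, rng):
        x = np.linspace(6, 17, 15)
        y = -0.6 * x - 3 + rng.normal(0, 1.5, size=15)
        band = fit_prediction_band(x, y, level=0.95)
        # independent evaluation of the textbook formula
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        s = math.sqrt(np.sum(resid**2) / (len(x) - 2))
        sxx = np.sum((x - x.mean()) ** 2)
        tcrit = sp_stats.t.ppf(0.975, len(x) - 2)
        for x0 in (8.0, 16.0):
            hw = tcrit * s * math.sqrt(1 + 1 / len(x) + (x0 - x.mean()) ** 2 / sxx)
            yhat = slope * x0 + intercept
            assert float(band.lower(x0)) == pytest.approx(yhat - hw, abs=1e-10)
            assert float(band.upper(x0)) == pytest.approx(yhat + hw, abs=1e-10)

    def test_empirical_coverage_95_pct(self):
        # fresh point from the generating model falls inside the 95% band
        # 95% of the time (within Monte-Carlo error)
        rng = np.random.default_rng(13)
        n, reps = 15, 10_000
        x = np.linspace(6, 17, n)
        inside = 0
        for _ in range(reps):
            y = -0.5 * x - 3 + rng.normal(0, 2, size=n)
            band = fit_prediction_band(x, y)
            x0 = rng.uniform(6, 17)
            y0 = -0.5 * x0 - 3 + rng.normal(0, 2)
            if band.lower(x0) <= y0 <= band.upper(x0):
                inside += 1
        assert abs(inside / reps - 0.95) <= 0.02

    def test_collinear_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_prediction_band([8.0, 8.0, 8.0], [1.0, 2.0, 3.0])


class TestFlagOutliers:
    def test_point_on_line_not_flagged(self, rng):
        x = np.linspace(6, 17, 15)
        y = -0.5 * x + rng.normal(0, 1, size=15)
        band = fit_prediction_band(x, y)
        assert flag_outliers(band, [(10.0, float(band.predict(10.0)))]) == []

    def test_far_point_flagged_with_side(self, rng):
        x = np.linspace(6, 17, 15)
        y = -0.5 * x + rng.normal(0, 1, size=15)
        band = fit_prediction_band(x, y)
        flags = flag_outliers(band, [(10.0, -100.0), (12.0, +100.0)])
        assert [f.side for f in flags] == ["below", "above"]

    def test_anomalous_listener_screens_out_in_antiphasic_condition(self):
        # a +15 dB antiphasic hardware advantage puts the listener far below
        # the band fitted to unaffected cohort data
        rng = np.random.default_rng(23)
        hits = 0
        reps = 200
        for _ in range(reps):
            ages = rng.uniform(6.7, 17.6, size=15)
            srts = -15.0 - 0.55 * (ages - 12.15) + rng.normal(0, 2.5, size=15)
            band = fit_prediction_band(ages, srts)
            age0 = rng.uniform(6.7, 17.6)
            srt0 = -15.0 - 0.55 * (age0 - 12.15) + rng.normal(0, 2.5) - 15.0
            flags = flag_outliers(band, [(age0, srt0)])
            if flags and flags[0].side == "below":
                hits += 1
        assert hits / reps >= 0.95


class TestAudibilityCheck:
    def test_comfortable_margin_not_flagged(self):
        res = audibility_check(-35.0, [-12.0, -8.0], masker_ref=0.0)
        assert res.margin == pytest.approx(23.0)
        assert res.flagged is False

    def test_boundary_margin_six_not_flagged(self):
        res = audibility_check(-16.0, [-10.0], masker_ref=0.0)
        assert res.margin == pytest.approx(6.0)
        assert res.flagged is False  # strict < 6 convention

    def test_small_margin_flagged(self):
        res = audibility_check(-10.0, [-8.0], masker_ref=0.0)
        assert res.margin == pytest.approx(2.0)
        assert res.flagged is True

    def test_missing_quiet_gives_missing_flag(self):
        res = audibility_check(float("nan"), [-10.0])
        assert res.flagged is None and res.margin is None

    def test_masker_reference_shifts_margin(self):
        assert audibility_check(-35.0, [-12.0], masker_ref=3.0).margin == (
            pytest.approx(26.0)
        )


@pytest.fixture(scope="module")
def small_study():
    cfg = preset_paper_day1()
    cfg.n_children, cfg.n_adults = 10, 6
    return simulate_study(cfg, np.random.default_rng(3), days=(1, 2))


class TestBuildReport:
    def test_report_structure(self, small_study):
        rep = build_report(small_study)
        assert rep.n_participants == {"child": 10, "adult": 6}
        assert "child/m0t0/day1" in rep.group_means
        assert "m0t0-day12" in rep.icc
        assert rep.icc["m0t0-day12"] is None or rep.icc["m0t0-day12"].n_subjects <= 16
        assert any(k.startswith("child_vs_adult/") for k in rep.group_tests)
        assert len(rep.audibility_flags) == 16 * 2
        assert rep.summary_text()

    def test_single_participant_has_means_but_no_icc(self):
        cfg = preset_paper_day1()
        cfg.n_children, cfg.n_adults = 1, 0
        study = simulate_study(cfg, np.random.default_rng(5), days=(1, 2))
        rep = build_report(study)
        assert "child/m0t0/day1" in rep.group_means
        assert rep.icc.get("m0t0-day12") is None

    def test_lab_mode_prediction_band_screening(self, small_study):
        cfg = preset_paper_day1()
        cfg.n_children, cfg.n_adults = 15, 0
        lab = simulate_study(cfg, np.random.default_rng(7), days=(1,))
        rep = build_report(small_study, lab_participants=lab)
        assert set(rep.outlier_flags) == {"m0t0", "m0tpi", "bild"}

    def test_report_json_export(self, small_study, tmp_path):
        rep = build_report(small_study)
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json

        with open(path) as fh:
            loaded = json.load(fh)
        assert "group_means" in loaded and "icc" in loaded
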