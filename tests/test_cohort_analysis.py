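"""Regression and classification stages of the cohort pipeline."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ffrsim import (
    CohortConfig,
    classify_dual_criterion,
    cohort_to_frame,
    correlate_ffrc_pd,
    fit_linear_pd_pa,
    fit_log_decomposition,
    fit_rational_ffr_pd,
    generate_cohort,
    gray_zone_fraction,
)
from ffrsim.cohort_analysis import RankDeficientDesignWarning, permutation_pvalue


def make_frame(PA, PD):
    """Minimal cohort frame from pressure arrays."""
    PA = np.asarray(PA, dtype=float)
    PD = np.asarray(PD, dtype=float)
    ffr = PD / PA
    return pd.DataFrame(
        {
            "id": [f"x{i}" for i in range(len(PA))],
            "location": ["m"] * len(PA),
            "alpha_true": np.nan,
            "S_pct": np.nan,
            "PA": PA,
            "PD_base": PD,
            "PD_hyper": PD,
            "FFR": ffr,
            "FFR_C": np.hypot(PA, PD),
            "clipped": False,
        }
    )


def _normal_equations(X, y):
    """Brute-force OLS oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestLinearFit:
    def test_exact_collinear_recovery(self):
        PA = np.linspace(60, 110, 10)
        fit = fit_linear_pd_pa(make_frame(PA, 0.9 * PA))
        assert fit.coefficients["slope"] == pytest.approx(0.9, rel=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.correlation == pytest.approx(1.0, rel=1e-10)

    def test_recovers_printed_regression_line(self):
        """Fixture built from the study's cohort line PD = 0.873 PA - 6.836."""
        PA = np.linspace(55, 115, 22)
        fit = fit_linear_pd_pa(make_frame(PA, 0.873 * PA - 6.836))
        assert fit.coefficients["slope"] == pytest.approx(0.873, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(-6.836, abs=1e-8)
        assert fit.r_squared == pytest.approx(fit.correlation**2, rel=1e-10)

    def test_agrees_with_normal_equations_oracle(self, rng):
        for _ in range(20):
            PA = rng.uniform(55, 115, 15)
            PD = 0.8 * PA - 5 + rng.normal(0, 4, 15)
            fit = fit_linear_pd_pa(make_frame(PA, PD))
            b = _normal_equations(np.column_stack([np.ones(15), PA]), PD)
            assert fit.coefficients["intercept"] == pytest.approx(b[0], rel=1e-8, abs=1e-8)
            assert fit.coefficients["slope"] == pytest.approx(b[1], rel=1e-8)

    def test_insufficient_or_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_linear_pd_pa(make_frame([100, 90], [80, 70]))
        with pytest.raises(ValueError):
            fit_linear_pd_pa(make_frame([100, 100, 100], [80, 75, 70]))


class TestRationalFit:
    def test_noiseless_recovery(self):
        PD = np.linspace(20, 100, 15)
        frame = make_frame(np.full(15, 1.0), PD)  # PA placeholder
        frame["FFR"] = PD / (20 + 0.8 * PD)
        fit = fit_rational_ffr_pd(frame)
        assert fit.coefficients["c1"] == pytest.approx(20, rel=1e-8)
        assert fit.coefficients["c2"] == pytest.approx(0.8, rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_pa_degenerates_to_line_through_origin(self):
        PD = np.linspace(30, 95, 12)
        fit = fit_rational_ffr_pd(make_frame(np.full(12, 100.0), PD))
        assert fit.coefficients["c1"] == pytest.approx(100.0, rel=1e-6)
        assert fit.coefficients["c2"] == pytest.approx(0.0, abs=1e-6)

    def test_fitted_curve_vanishes_at_origin(self):
        from ffrsim.cohort_analysis import _rational

        assert _rational(0.0, 37.2, 0.55) == 0.0

    def test_random_coefficient_recovery_and_noise_robustness(self, rng):
        """Noiseless random (c1, c2) recovered to high precision; with FFR
        noise of sd 0.02 the median relative error stays below 10%."""
        rel_errs_clean, rel_errs_noisy = [], []
        for _ in range(50):
            c1 = rng.uniform(5, 50)
            c2 = rng.uniform(0.3, 1.2)
            PD = rng.uniform(15, 110, 22)
            ffr = PD / (c1 + c2 * PD)
            for noisy in (False, True):
                frame = make_frame(np.full(22, 1.0), PD)
                frame["FFR"] = ffr + (rng.normal(0, 0.02, 22) if noisy else 0)
                frame = frame[frame["FFR"] > 0]
                fit = fit_rational_ffr_pd(frame)
                err = max(
                    abs(fit.coefficients["c1"] - c1) / c1,
                    abs(fit.coefficients["c2"] - c2) / c2,
                )
                (rel_errs_noisy if noisy else rel_errs_clean).append(err)
        assert max(rel_errs_clean) < 1e-6
        assert np.median(rel_errs_noisy) < 0.10

    def test_nonpositive_ffr_records_excluded_with_warning(self):
        frame = make_frame([100] * 5, [80, 70, 60, 50, 40])
        frame.loc[0, "FFR"] = -0.1
        with pytest.warns(UserWarning, match="excluded 1"):
            fit = fit_rational_ffr_pd(frame)
        assert fit.n == 4


class TestCompanionCorrelation:
    def test_constant_pa_gives_perfect_correlation(self):
        """At fixed PA, FFR_C is strictly increasing in PD... but linearly so
        only approximately; Pearson R is still 1 within tolerance on a
        narrow PD range and near 1 globally."""
        PD = np.linspace(30, 95, 12)
        fit = correlate_ffrc_pd(make_frame(np.full(12, 100.0), PD))
        assert fit.correlation > 0.99

    def test_constructed_zero_correlation(self):
        """PD values mirrored within equal-FFR_C pairs: covariance cancels."""
        PD = np.array([40.0, 60.0, 40.0, 60.0])
        FC = np.array([100.0, 100.0, 120.0, 120.0])
        PA = np.sqrt(FC**2 - PD**2)
        frame = make_frame(PA, PD)
        frame["FFR_C"] = FC
        fit = correlate_ffrc_pd(frame)
        # brute-force correlation oracle
        ref = np.corrcoef(PD, FC)[0, 1]
        assert fit.correlation == pytest.approx(ref, abs=1e-12)
        assert fit.correlation == pytest.approx(0.0, abs=1e-12)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            correlate_ffrc_pd(make_frame([100, 90], [70, 60]))


class TestLogDecomposition:
    def test_exact_ratio_data_gives_identity_coefficients(self, rng):
        PA = rng.uniform(60, 120, 30)
        PD = rng.uniform(20, 55, 30)  # varied independently of PA
        fit = fit_log_decomposition(make_frame(PA, PD))
        assert fit.coefficients["A"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["B"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["C"] == pytest.approx(0.0, abs=1e-9)
        assert fit.stderr is not None

    def test_agrees_with_normal_equations_oracle(self, rng):
        PA = rng.uniform(60, 120, 25)
        PD = 0.8 * PA * np.exp(rng.normal(0, 0.05, 25))
        frame = make_frame(PA, PD)
        fit = fit_log_decomposition(frame)
        X = np.column_stack([np.ones(25), np.log(PD), np.log(PA)])
        b = _normal_equations(X, np.log(PD / PA))
        assert fit.coefficients["C"] == pytest.approx(b[0], rel=1e-8, abs=1e-8)
        assert fit.coefficients["A"] == pytest.approx(b[1], rel=1e-8)
        assert fit.coefficients["B"] == pytest.approx(-b[2], rel=1e-8)

    def test_constant_pa_triggers_rank_warning(self):
        PD = np.linspace(30, 90, 10)
        with pytest.warns(RankDeficientDesignWarning):
            fit = fit_log_decomposition(make_frame(np.full(10, 100.0), PD))
        assert fit.coefficients["A"] == pytest.approx(1.0, abs=1e-8)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            fit_log_decomposition(make_frame([100, 90, 80], [70, 60, 50]))


class TestClassification:
    def test_boundary_ffr_not_abnormal_but_jeopardy(self):
        """FFR exactly 0.80 passes the FFR criterion, yet PD = 40 < 50 mmHg
        flags the record as in jeopardy."""
        res = classify_dual_criterion(make_frame([50.0], [40.0]))
        row = res.flags.iloc[0]
        assert not row["below_ffr_cut"]
        assert row["below_pd_cut"]
        assert row["jeopardy"]

    def test_all_healthy_cohort_has_zero_flags(self):
        res = classify_dual_criterion(make_frame([95.0] * 4, [95.0] * 4))
        assert res.counts["below_ffr_cut"] == 0
        assert res.counts["below_pd_cut"] == 0
        assert res.counts["jeopardy"] == 0

    def test_gray_zone_membership(self):
        res = classify_dual_criterion(make_frame([100.0], [76.0]))
        assert res.flags.iloc[0]["in_gray_zone"]

    def test_jeopardy_disjoint_from_below_cut_and_permutation_invariant(self, default_cohort):
        frame = cohort_to_frame(default_cohort)
        res = classify_dual_criterion(frame)
        both = res.flags["jeopardy"] & res.flags["below_ffr_cut"]
        assert not both.any()
        shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = classify_dual_criterion(shuffled)
        assert res.counts == res2.counts

    def test_optional_companion_cutoff(self):
        frame = make_frame([100.0, 100.0], [85.0, 95.0])
        res = classify_dual_criterion(frame, ffrc_cut=135.0)
        assert res.flags.iloc[0]["below_ffrc_cut"]
        assert res.flags.iloc[0]["jeopardy"]  # FFR 0.85 fine, FFR_C low
        assert not res.flags.iloc[1]["jeopardy"]


class TestGrayZone:
    def test_default_zone_is_five_percent_of_range(self):
        report = gray_zone_fraction(make_frame([100.0], [90.0]))
        assert report.zone_width == pytest.approx(0.05)

    def test_half_open_membership(self):
        frame = make_frame([100.0] * 4, [74.0, 75.0, 79.0, 80.0])
        report = gray_zone_fraction(frame)
        assert report.fraction == pytest.approx(0.5)
        assert report.n_in_zone == 2

    def test_no_records_in_zone(self):
        assert gray_zone_fraction(make_frame([100.0], [90.0])).fraction == 0.0

    def test_bad_bounds_and_empty(self):
        with pytest.raises(ValueError):
            gray_zone_fraction(make_frame([100.0], [90.0]), lo=0.9, hi=0.8)
        with pytest.raises(ValueError):
            gray_zone_fraction(make_frame([], []))


class TestPermutationPValue:
    def test_strong_association_is_significant(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 2 * x + rng.normal(0, 0.05, 30)
        assert permutation_pvalue(x, y, n_perm=499, seed=0) < 0.01

    def test_pure_noise_is_not(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0, 1, 30)
        assert permutation_pvalue(x, y, n_perm=499, seed=0) > 0.05


class TestEndToEndOnSyntheticCohort:
    def test_full_suite_runs_on_default_cohort(self, default_cohort):
        frame = cohort_to_frame(default_cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = [
                fit_linear_pd_pa(frame),
                fit_rational_ffr_pd(frame),
                correlate_ffrc_pd(frame),
                fit_log_decomposition(frame),
            ]
        for fit in fits:
            assert fit.n >= 3
            assert math.isfinite(fit.r_squared)
        # companion tracks the distal pressure strongly, as in the study
        assert correlate_ffrc_pd(frame).correlation > 0.8
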