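"""Exponential calibration, cross-validation, and the supporting statistics."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perfviz import lactate
from perfviz.errors import DimensionError, ParameterError
from perfviz.lactate import (
    ExponentialModel,
    compare_models_wilcoxon,
    error_summary,
    fit_exponential,
    loo_cv,
    normalize_lcl,
    predict_lcl,
    sample_size_correlation,
    spearman_correlation,
)
from perfviz.synthgen import CohortParams, generate_cohort


class TestNormalizeAndPredict:
    def test_subtracts_systemic_elementwise(self):
        out = normalize_lcl([10.2, 3.0, 1.87], [1.87, 3.0, 1.87])
        np.testing.assert_allclose(out, [8.33, 0.0, 0.0])

    def test_printed_equation_at_zero_predictor(self):
        model = ExponentialModel(0.0343, 2.72, "sto2")
        assert predict_lcl(model, 0.0, 0.0) == pytest.approx(np.exp(2.72))

    def test_prediction_decreasing_and_bounded_below_by_systemic(self):
        model = ExponentialModel(0.0343, 2.72, "sto2")
        x = np.linspace(0, 100, 50)
        pred = predict_lcl(model, x, 1.87)
        assert np.all(np.diff(pred) < 0)
        assert np.all(pred > 1.87)
        assert predict_lcl(model, 1e6, 1.87) == pytest.approx(1.87)

    def test_log_linearity_of_local_excess(self):
        model = ExponentialModel(0.403, 2.32, "fler_slope")
        x = np.linspace(0.1, 8, 30)
        log_excess = np.log(model.local_excess(x))
        np.testing.assert_allclose(log_excess, -0.403 * x + 2.32, rtol=1e-12)


class TestFit:
    @pytest.mark.parametrize("a,b", [(0.0343, 2.72), (0.403, 2.32)])
    def test_noise_free_recovery_to_1e6(self, a, b):
        x = np.linspace(0.5, 80 if a < 0.1 else 8, 40)
        y = np.exp(-a * x + b)
        model = fit_exponential(x, y)
        assert model.a == pytest.approx(a, abs=1e-6)
        assert model.b == pytest.approx(b, abs=1e-6)

    def test_constant_positive_y_gives_log_intercept(self):
        x = np.linspace(0, 10, 20)
        model = fit_exponential(x, np.full(20, 3.5))
        assert model.a == pytest.approx(0.0, abs=1e-6)
        assert model.b == pytest.approx(np.log(3.5), abs=1e-6)

    def test_negative_normalized_values_are_legal(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 80, 30)
        y = np.exp(-0.05 * x + 1.0) + rng.normal(0, 0.5, 30)  # some y < 0
        assert (y < 0).any()
        model = fit_exponential(x, y)
        assert np.isfinite(model.a) and np.isfinite(model.b)

    def test_monte_carlo_recovery_under_lognormal_noise(self):
        """n=60 subjects, log-scale noise SD 0.3: median relative error in the
        decay rate stays below 25% over 200 replicates."""
        errs = []
        for rep in range(200):
            cohort = generate_cohort(CohortParams(n_subjects=60, seed=rep),
                                     lcl_noise_sd=0.3)
            y = normalize_lcl(cohort["lcl_mmol_l"],
                              cohort["systemic_lactate_mmol_l"])
            model = fit_exponential(cohort["sto2_pct"], y)
            errs.append(abs(model.a - 0.0343) / 0.0343)
        assert np.median(errs) < 0.25

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            fit_exponential([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ParameterError):
            fit_exponential([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestCrossValidation:
    def _cohort(self, n, seed=0, noise=0.0):
        return generate_cohort(CohortParams(n_subjects=n, seed=seed),
                               lcl_noise_sd=noise)

    def test_noise_free_cohort_errors_vanish(self):
        cv = loo_cv(self._cohort(6), predictor="sto2")
        assert cv["abs_error"].max() < 1e-6

    def test_six_subjects_six_folds_18_errors(self):
        cv = loo_cv(self._cohort(6, noise=0.2), predictor="sto2")
        assert len(cv) == 18
        assert cv["subject_id"].nunique() == 6

    def test_subject_permutation_invariance(self):
        cohort = self._cohort(5, seed=3, noise=0.2)
        shuffled = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = loo_cv(cohort, "sto2").sort_values(["subject_id", "roi_label"])
        b = loo_cv(shuffled, "sto2").sort_values(["subject_id", "roi_label"])
        # row order changes the optimizer's summation order; identical up to
        # convergence tolerance, not bit-exactly
        np.testing.assert_allclose(a["abs_error"].to_numpy(),
                                   b["abs_error"].to_numpy(),
                                   rtol=1e-4, atol=1e-6)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            loo_cv(self._cohort(2), "sto2")


class TestErrorSummary:
    def test_constant_errors(self):
        s = error_summary([2.0, 2.0, 2.0], [5.0, 6.0, 7.0])
        assert (s.mean, s.sd, s.median) == (2.0, 0.0, 2.0)

    def test_median_of_three(self):
        assert error_summary([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]).median == 2.0

    def test_q95_threshold_is_lcl_percentile(self):
        lcls = np.arange(1.0, 101.0)
        s = error_summary(np.ones(100), lcls)
        assert s.q95_threshold == pytest.approx(np.percentile(lcls, 95))

    def test_mean_error_matches_folded_noise_expectation(self):
        """Errors |e^eps - 1|*mu with eps ~ N(0, sd): Monte-Carlo mean within
        3 standard errors of the analytic expectation."""
        rng = np.random.default_rng(5)
        sd, mu, n = 0.3, 4.0, 20_000
        errors = np.abs(np.exp(rng.normal(0, sd, n)) - 1) * mu
        # numerical-quadrature oracle for E|e^X - 1|, X ~ N(0, sd^2)
        grid = np.linspace(-6 * sd, 6 * sd, 20_001)
        pdf = stats.norm.pdf(grid, scale=sd)
        expected = mu * np.trapezoid(np.abs(np.exp(grid) - 1) * pdf, grid)
        summary = error_summary(errors, np.full(n, mu))
        sem = errors.std(ddof=1) / np.sqrt(n)
        assert abs(summary.mean - expected) < 3 * sem

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            error_summary([1.0, 2.0], [1.0])


class TestWilcoxon:
    def test_identical_errors_degenerate_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w, p = compare_models_wilcoxon(a, a.copy())
        assert p == 1.0

    def test_uniform_shift_gives_smallest_attainable_p(self):
        a = np.arange(1.0, 11.0)
        w, p = compare_models_wilcoxon(a, a + 1.0)
        assert w == 0.0
        assert p == pytest.approx(2 / 2**10)

    def test_matches_full_enumeration_for_n10(self):
        """Exact p equals brute-force enumeration of all 2^10 sign patterns."""
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 5, 10)
        b = a + rng.uniform(-2, 2, 10)
        w_obs, p_obs = compare_models_wilcoxon(a, b)
        diff = a - b
        ranks = stats.rankdata(np.abs(diff))
        stats_all = [sum(r for r, s in zip(ranks, signs) if s > 0)
                     for signs in itertools.product([-1, 1], repeat=10)]
        stats_all = np.asarray(stats_all, dtype=float)
        p_low = np.mean(stats_all <= w_obs + 1e-9)
        p_high = np.mean(stats_all >= w_obs - 1e-9)
        p_enum = min(1.0, 2 * min(p_low, p_high))
        assert p_obs == pytest.approx(p_enum, abs=1e-12)

    def test_agrees_with_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        a = rng.normal(2, 1, 12)
        b = a + rng.normal(0.3, 0.7, 12)
        _, p = compare_models_wilcoxon(a, b)
        ref = stats.wilcoxon(a, b, method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(2, 1, 40)
        b = a + rng.normal(0.2, 0.5, 40)
        _, p = compare_models_wilcoxon(a, b)
        ref = stats.wilcoxon(a, b, method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearman:
    def test_perfect_monotone_relationships(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        rho, _ = spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0, abs=1e-12)
        rho, _ = spearman_correlation(x, -x)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_ties_match_average_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        rho, _ = spearman_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # average ranks
        manual = np.corrcoef(rx, ry)[0, 1]  # Pearson on ranks
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            spearman_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ParameterError):
            spearman_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSampleSize:
    def test_reproduces_required_13_pairs(self):
        assert sample_size_correlation(0.78, 0.05, 0.90) == 13

    def test_floor_as_r_approaches_one(self):
        assert sample_size_correlation(0.999999, 0.05, 0.90) == 4

    def test_monotone_in_power_and_r(self):
        assert (sample_size_correlation(0.5, 0.05, 0.9)
                >= sample_size_correlation(0.5, 0.05, 0.8))
        assert (sample_size_correlation(0.5, 0.05, 0.9)
                >= sample_size_correlation(0.9, 0.05, 0.9))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sample_size_correlation(1.0)
        with pytest.raises(ParameterError):
            sample_size_correlation(0.5, alpha=0.0)

    @pytest.mark.parametrize("r", [0.5, 0.7, 0.78, 0.9])
    def test_agrees_with_simulated_power_search(self, r):
        """Brute-force power search (Fisher-z test on simulated bivariate
        normal data) finds a minimal n within +/-1 of the formula."""
        n_formula = sample_size_correlation(r, 0.05, 0.90)
        rng = np.random.default_rng(17)
        z_crit = stats.norm.ppf(0.975)
        reps = 4000
        cov = np.array([[1.0, r], [r, 1.0]])
        chol = np.linalg.cholesky(cov)

        def power(n):
            xy = rng.standard_normal((reps, n, 2)) @ chol.T
            x, y = xy[..., 0], xy[..., 1]
            xc = x - x.mean(1, keepdims=True)
            yc = y - y.mean(1, keepdims=True)
            rr = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
            rr = np.clip(rr, -0.999999, 0.999999)
            z = 0.5 * np.log((1 + rr) / (1 - rr)) * np.sqrt(n - 3)
            return np.mean(np.abs(z) > z_crit)

        lo, hi = max(n_formula - 4, 5), n_formula + 4
        n_brute = next((n for n in range(lo, hi + 1) if power(n) >= 0.90), hi + 1)
        assert abs(n_brute - n_formula) <= 1
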