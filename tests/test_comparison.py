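"""Baselines and the three-way logistic-regression comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.metrics import adjusted_rand_score

from koaprog import (
    SeparationError,
    SubtypeProgressionModel,
    fit_gaussian_mixture,
    fit_stages_only,
    likelihood_ratio_test,
    logistic_fit,
    run_comparison,
)
from koaprog.assignment import assign
from conftest import make_cohort, make_sim_event_set


class TestGaussianMixture:
    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, size=(150, 3))
        b = rng.normal(10.0, 1.0, size=(150, 3))
        Z = pd.DataFrame(np.vstack([a, b]))
        truth = np.r_[np.zeros(150), np.ones(150)]
        grade = np.full(300, 3)  # everyone OA: mixture sees all subjects
        fit = fit_gaussian_mixture(Z, grade, k=2, n_starts=4, seed=0)
        assert adjusted_rand_score(truth, fit.labels_all) >= 0.99

    def test_single_component_equals_sample_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 1.5, size=(400, 2))
        fit = fit_gaussian_mixture(pd.DataFrame(X), np.full(400, 2), k=1, n_starts=1)
        np.testing.assert_allclose(fit.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(fit.variances[0], X.var(axis=0), atol=1e-4)

    def test_em_trace_monotone(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.normal(0, 1, (100, 2)), rng.normal(3, 1, (100, 2))]
        )
        fit = fit_gaussian_mixture(pd.DataFrame(X), np.full(200, 2), k=2, n_starts=3)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_only_diseased_subjects_used_for_fitting(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(200, 2))
        X[:100] += 50.0  # grade 0/1 subjects far away
        grade = np.r_[np.zeros(100), np.full(100, 3)]
        fit = fit_gaussian_mixture(pd.DataFrame(X), grade, k=1, n_starts=1)
        np.testing.assert_allclose(fit.means[0], X[100:].mean(axis=0), atol=1e-6)
        assert len(fit.labels_all) == 200


class TestStagesOnly:
    def test_equals_single_subtype_fit(self, es4):
        cohort = make_cohort(es4, fractions=(1.0,), n=80, seed=0)
        a = fit_stages_only(cohort.z_values, es4, n_starts=4, seed=5)
        b = SubtypeProgressionModel(
            event_set=es4, n_subtypes=1, n_starts=4, random_state=5
        ).fit(cohort.z_values)
        assert a.sequences_[0].order == b.sequences_[0].order
        assert a.loglik_ == pytest.approx(b.loglik_)

    def test_nested_in_larger_model(self, es10):
        cohort = make_cohort(es10, n=200, seed=1, reversed_pair=True)
        one = fit_stages_only(cohort.z_values, es10, n_starts=3, seed=0)
        three = SubtypeProgressionModel(
            event_set=es10, n_subtypes=3, n_starts=3, random_state=0
        ).fit(cohort.z_values)
        assert one.loglik_ <= three.loglik_ + 1e-6

    def test_stage_estimates_track_truth(self):
        # full 13-biomarker panel: 33 stages give fine temporal resolution
        from koaprog.reference import koa_event_set

        es = koa_event_set()
        cohort = make_cohort(es, fractions=(1.0,), n=500, noise_sd=1.0, seed=2)
        model = fit_stages_only(cohort.z_values, es, n_starts=2, seed=0)
        post = assign(cohort.z_values, model)
        from scipy.stats import spearmanr

        rho = spearmanr(
            [p.ml_stage for p in post], cohort.truth_stage
        ).statistic
        assert rho >= 0.9


class TestLogisticFit:
    def test_two_by_two_closed_form(self):
        # cells (a, b, c, d) = (30, 10, 10, 30): slope = log(ad / bc) = log 9
        x = np.r_[np.zeros(40), np.ones(40)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)]
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(-np.log(9), abs=1e-6)
        assert fit.loglik <= 0
        lo, hi = fit.conf_int.loc["x"]
        assert lo <= fit.params["x"] <= hi

    def test_independent_predictor_ci_covers_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        lo, hi = fit.conf_int.loc["x"]
        assert lo < 0 < hi

    def test_perfect_separation_raises_with_predictor_name(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError, match="'x'"):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_matches_direct_likelihood_maximization(self):
        """Oracle: directly maximize the Bernoulli log likelihood with a
        generic optimizer and compare coefficients."""
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        eta = -0.3 + 1.2 * x1 - 0.7 * x2
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        fit = logistic_fit(y, X)
        D = np.column_stack([np.ones(300), x1, x2])

        def nll(beta):
            eta = D @ beta
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        res = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-4)


class TestLikelihoodRatio:
    def test_equal_likelihoods(self):
        stat, p = likelihood_ratio_test(-10.0, -10.0, df=1)
        assert stat == 0.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,expected_p", [(3.841, 0.050), (6.635, 0.010)])
    def test_chi_square_quantiles(self, stat, expected_p):
        got_stat, p = likelihood_ratio_test(-100.0 + stat / 2, -100.0, df=1)
        assert got_stat == pytest.approx(stat)
        assert p == pytest.approx(expected_p, abs=5e-4)

    def test_negative_statistic_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            stat, p = likelihood_ratio_test(-11.0, -10.0, df=1)
        assert stat == 0.0 and p == 1.0

    def test_df_validated(self):
        with pytest.raises(ValueError, match="df"):
            likelihood_ratio_test(-1.0, -2.0, df=0)


class TestRunComparison:
    def _cohort_and_models(self, seed=0, n=500):
        es = make_sim_event_set(5)
        cohort = make_cohort(
            es, fractions=(0.5, 0.5), n=n, noise_sd=1.0, seed=seed,
            reversed_pair=True, grade_flip_prob=0.05,
            severity_thresholds=(1, 4, 7, 9),  # grade boundary mid-course
        )
        prog = SubtypeProgressionModel(
            event_set=es, n_subtypes=2, n_starts=4, split_starts=3,
            random_state=seed,
        ).fit(cohort.z_values)
        stages = fit_stages_only(cohort.z_values, es, n_starts=4, seed=seed)
        mix = fit_gaussian_mixture(
            cohort.z_values, cohort.severity_grade, k=2, n_starts=4, seed=seed
        )
        return cohort, prog, stages, mix

    def test_structured_cohort_prefers_progression_model(self):
        cohort, prog, stages, mix = self._cohort_and_models(seed=1)
        res = run_comparison(
            cohort.z_values,
            cohort.severity_grade,
            cohort.demographics,
            prog,
            stages,
            mix,
        )
        assert res.fits["progression"].params["stages"] > 0
        stat, p, df = res.lr_tests["progression_vs_subtypes_only"]
        assert stat > 0
        assert res.metadata["non_nested_comparison"] is True

    def test_identical_arms_give_zero_lr(self):
        stat, p = likelihood_ratio_test(-55.5, -55.5, df=1)
        assert stat == 0.0 and p == 1.0

    def test_null_cohort_gives_small_lr_against_mixture(self):
        """Pure-noise biomarkers carry no progression signal, so adding the
        progression stage/subtype cannot systematically beat the mixture arm."""
        es = make_sim_event_set(3)
        rng = np.random.default_rng(6)
        n = 240
        hits = 0
        for seed in range(3):
            Z = pd.DataFrame(
                rng.normal(1.0, 1.0, size=(n, 3)), columns=es.biomarkers
            )
            grade = rng.integers(0, 5, size=n)
            demo = pd.DataFrame(
                {
                    "age": rng.normal(62, 9, n),
                    "gender": rng.integers(0, 2, n),
                    "bmi": rng.normal(29, 4.7, n),
                    "injury": rng.integers(0, 2, n),
                }
            )
            prog = SubtypeProgressionModel(
                event_set=es, n_subtypes=2, n_starts=2, random_state=seed
            ).fit(Z)
            stages = fit_stages_only(Z, es, n_starts=2, seed=seed)
            mix = fit_gaussian_mixture(Z, grade, k=2, n_starts=2, seed=seed)
            res = run_comparison(Z, grade, demo, prog, stages, mix)
            _, p, _ = res.lr_tests["progression_vs_subtypes_only"]
            hits += p > 0.05
        assert hits >= 2
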