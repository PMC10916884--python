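import numpy as np
import pandas as pd
import pytest

from foveaspec.model import (
    CANDIDATE_TERMS,
    FIXED_COEFFICIENTS,
    FIXED_SPEC,
    FIXED_TERMS,
    LinearModelSpec,
    accuracy_within,
    design_matrix,
    encode_age18,
    fit_categorical_model,
    fit_linear_model,
    fixed_equation_predict,
    loocv,
    loocv_residuals_hat,
    stepwise_select,
)
from foveaspec.synthetic import CohortParams, generate_cohort


class TestEncodeAge18:
    @pytest.mark.parametrize("age, expected",
                             [(18, 0), (19, 1), (5, 0), (75, 1), (0, 0)])
    def test_boundary(self, age, expected):
        assert encode_age18(age) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            encode_age18(-1)


class TestFixedEquation:
    @pytest.mark.parametrize(
        "irl, os_, onl, age18, expected",
        [
            (0.0, 0.0, 0.0, 0, 1.128),                   # intercept only
            (1.0, 1.0, 1.0, 0, 0.734),                   # hand evaluation
            (1.0, 1.0, 1.0, 1, 0.757),                   # hand evaluation
            (2.0, 1.0, 1.0, 0, 0.865),                   # 0.734 + 0.131
            (1.0, 2.0, 1.0, 0, 0.285),                   # 0.734 − 0.449
            (1.0, 1.0, 2.0, 1, 0.681),                   # 0.757 − 0.076
            (2.0, 2.0, 2.0, 1, -0.010),
        ],
    )
    def test_printed_equation_points(self, irl, os_, onl, age18, expected):
        value = fixed_equation_predict(irl, os_, onl, age18)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_vectorized_evaluation(self):
        out = fixed_equation_predict(np.ones(3), np.ones(3), np.ones(3),
                                     np.array([0, 1, 0]))
        np.testing.assert_allclose(out, [0.734, 0.757, 0.734], atol=1e-12)

    def test_nonbinary_age_rejected(self):
        with pytest.raises(ValueError):
            fixed_equation_predict(1.0, 1.0, 1.0, 2)


class TestFitLinearModel:
    def test_recovers_printed_coefficients_on_noiseless_cohort(
            self, noiseless_cohort):
        fit = fit_linear_model(noiseless_cohort, FIXED_SPEC)
        for term, value in fit.coefficients.items():
            assert value == pytest.approx(FIXED_COEFFICIENTS[term], abs=1e-8)
        assert fit.cv_rmse <= 1e-8

    def test_constant_response_gives_zero_slopes(self):
        df = generate_cohort(CohortParams(n_participants=50, seed=1))
        df["bcva_logmar"] = 0.5
        fit = fit_linear_model(df, LinearModelSpec(("irl", "os")))
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.coefficients["irl"] == pytest.approx(0.0, abs=1e-10)
        assert fit.coefficients["os"] == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_r2_identity_with_zero_predictors(self, noisy_cohort):
        fit = fit_linear_model(noisy_cohort, LinearModelSpec(()))
        assert fit.adj_r2 == pytest.approx(fit.r2)
        assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_rank_deficiency_reported(self, noisy_cohort):
        df = noisy_cohort.copy()
        df["sex"] = df["age18"]  # perfect collinearity
        with pytest.raises(ValueError, match="rank"):
            fit_linear_model(df, LinearModelSpec(("age18", "sex")))

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            LinearModelSpec(("irl", "irl"))


class TestLOOCV:
    def test_intercept_only_predictions_are_leave_one_out_means(
            self, noisy_cohort):
        y = noisy_cohort["bcva_logmar"].to_numpy()
        preds, _, _ = loocv(noisy_cohort, LinearModelSpec(()))
        n = y.size
        expected = (y.sum() - y) / (n - 1)
        np.testing.assert_allclose(preds, expected, atol=1e-10)

    def test_residuals_match_hat_matrix_closed_form(self, noisy_cohort):
        for terms in [FIXED_TERMS, ("irl",), ("irl", "os", "onl", "sex")]:
            spec = LinearModelSpec(tuple(terms))
            y = noisy_cohort["bcva_logmar"].to_numpy()
            preds, _, _ = loocv(noisy_cohort, spec)
            closed = loocv_residuals_hat(noisy_cohort, spec)
            np.testing.assert_allclose(y - preds, closed, atol=1e-10)

    def test_zero_noise_cohort_has_zero_cv_error(self, noiseless_cohort):
        _, rmse, r = loocv(noiseless_cohort, FIXED_SPEC)
        assert rmse <= 1e-8
        assert r == pytest.approx(1.0, abs=1e-8)


class TestCategoricalModel:
    def test_fitted_values_are_grade_means(self, noisy_cohort):
        fit = fit_categorical_model(noisy_cohort)
        y = noisy_cohort["bcva_logmar"]
        for g, sub in noisy_cohort.groupby("grade"):
            fitted = fit.coefficients["intercept"] + fit.coefficients.get(
                f"grade[{g}]", 0.0)
            assert fitted == pytest.approx(sub["bcva_logmar"].mean(), abs=1e-10)

    def test_two_grade_dummy_coefficient(self):
        df = pd.DataFrame({
            "grade": ["1a"] * 4 + ["2"] * 4,
            "bcva_logmar": [0.3] * 4 + [0.7] * 4,
        })
        fit = fit_categorical_model(df)
        assert fit.coefficients["grade[2]"] == pytest.approx(0.4)

    def test_singleton_grade_excluded_from_cv(self):
        df = pd.DataFrame({
            "grade": ["1a"] * 5 + ["4"],
            "bcva_logmar": list(np.linspace(0.2, 0.6, 5)) + [0.9],
        })
        fit = fit_categorical_model(df)
        assert any(f.startswith("loocv_undefined") for f in fit.flags)
        assert np.isnan(fit.cv_predictions[-1])

    def test_recovers_generator_grade_means_within_noise(self):
        # per-grade generation: fitted grade means approach the noise-free
        # acuity means implied by the generating equation, within ~4 SE
        params = CohortParams(n_participants=400, seed=6, mode="per_grade")
        cohort = generate_cohort(params)
        truth = fixed_equation_predict(
            cohort["irl_ratio"], cohort["os_ratio"], cohort["onl_ratio"],
            cohort["age18"])
        fit = fit_categorical_model(cohort)
        for g, sub in cohort.groupby("grade"):
            fitted = fit.coefficients["intercept"] + fit.coefficients.get(
                f"grade[{g}]", 0.0)
            se = params.noise_sd_logmar / np.sqrt(len(sub))
            assert abs(fitted - truth[cohort["grade"] == g].mean()) <= 4 * se


class TestStepwise:
    def test_noiseless_cohort_recovers_printed_terms(self, noiseless_cohort):
        spec, trace = stepwise_select(noiseless_cohort)
        assert set(spec.terms) == set(FIXED_TERMS)
        assert trace[0]["action"] == "start"

    def test_single_informative_term_selected(self):
        rng = np.random.default_rng(0)
        n = 120
        df = pd.DataFrame({
            "irl_ratio": rng.uniform(1, 2.6, n),
            "os_ratio": rng.uniform(1, 2.4, n),
            "onl_ratio": rng.uniform(1, 2.9, n),
            "sex": rng.integers(0, 2, n),
            "age18": rng.integers(0, 2, n),
        })
        df["bcva_logmar"] = 1.0 - 0.5 * df["os_ratio"]
        spec, _ = stepwise_select(df)
        assert spec.terms == ("os",)

    def test_candidate_limit_enforced(self, noisy_cohort):
        with pytest.raises(ValueError, match="20"):
            stepwise_select(noisy_cohort, tuple(f"irl:{'x' * i}" for i in range(21)))


class TestAccuracyWithin:
    def test_fraction_within_band(self):
        obs = np.array([0.0, 0.0, 0.0, 0.0])
        pred = np.array([0.05, 0.15, 0.25, 0.35])
        assert accuracy_within(obs, pred, 0.2) == pytest.approx(0.5)
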