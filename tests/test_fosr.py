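"""Function-on-scalar regression: fitting, tests, R^2 family, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from netpercolate import (
    ConfigurationError,
    FunctionOnScalarRegression,
    build_design_matrix,
    fit_fosr,
    simulate_functional_cohort,
)
from netpercolate.types import FunctionalSample


def _fit_cohort(n=80, age_effect=0.0, mean_function="rising", noise=0.05, seed=0,
                **kwargs):
    cov, fs = simulate_functional_cohort(
        n_subjects=n, age_effect=age_effect, mean_function=mean_function,
        noise_sd=noise, seed=seed,
    )
    X = build_design_matrix(cov)
    return fit_fosr(fs, X, **kwargs), fs, X


class TestDesignMatrix:
    def test_columns_and_reference_levels(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "age_years": [5.0, 10.0, 15.0],
                "sex": ["female", "male", "female"],
                "handedness": ["right", "left", "no_preference"],
                "mean_node_distance": [80.0, 82.0, 84.0],
            }
        )
        x = build_design_matrix(df)
        assert list(x.columns) == [
            "age", "sex_female", "hand_left", "hand_no_preference", "distance",
        ]
        assert x["age"].mean() == pytest.approx(0.0)  # centered
        np.testing.assert_array_equal(x["hand_left"], [0, 1, 0])
        np.testing.assert_array_equal(x["hand_no_preference"], [0, 0, 1])

    def test_collinear_design_names_offending_column(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=20)})
        x["b"] = 2 * x["a"]
        y = rng.normal(size=(20, 12))
        model = FunctionOnScalarRegression()
        with pytest.raises(ConfigurationError, match="collinear"):
            model.fit(x, y)


class TestFitting:
    def test_constant_response_recovers_constant_intercept(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 1))
        y = np.full((30, 20), 2.0)  # no covariate effect, no noise
        model = FunctionOnScalarRegression(densities=np.linspace(0.01, 0.3, 20))
        model.fit(x, y)
        assert np.abs(model.coef_[0] - 2.0).max() < 1e-6
        assert np.abs(model.coef_[1]).max() < 1e-6

    def test_constant_age_effect_recovered_within_tolerance(self):
        fit, _, _ = _fit_cohort(n=80, age_effect=-0.01, seed=2)
        beta = fit.coef_[fit.coef_names_.index("age")]
        assert np.abs(beta - (-0.01)).max() < 0.003

    def test_matches_pointwise_ols_with_saturated_basis_and_tiny_penalty(self):
        rng = np.random.default_rng(3)
        n, m = 40, 12
        d = np.linspace(0.01, 0.3, m)
        x = rng.normal(size=(n, 2))
        y = 0.5 + x @ rng.normal(size=(2, m)) * 0.1 + 0.05 * rng.normal(size=(n, m))
        model = FunctionOnScalarRegression(
            densities=d, n_basis=m, lambda_grid=[1e-8]
        )
        model.fit(x, y)
        x_aug = np.column_stack([np.ones(n), x])
        ols = np.linalg.lstsq(x_aug, y, rcond=None)[0]  # (p+1, m) per-density
        np.testing.assert_allclose(model.coef_, ols, atol=1e-4)

    def test_predict_reproduces_fitted_values(self):
        fit, fs, X = _fit_cohort(n=30, seed=4)
        np.testing.assert_allclose(fit.predict(X), fit.fitted_)

    def test_sklearn_param_roundtrip(self):
        model = FunctionOnScalarRegression(n_basis=7, alpha=0.01)
        params = model.get_params()
        clone = FunctionOnScalarRegression().set_params(**params)
        assert clone.n_basis == 7 and clone.alpha == 0.01


class TestOverallTest:
    def test_power_against_density_varying_age_effect(self):
        # beta_age(d) varies strongly over the domain
        rng = np.random.default_rng(5)
        cov, fs = simulate_functional_cohort(n_subjects=80, noise_sd=0.05, seed=5)
        age_c = cov["age_years"] - cov["age_years"].mean()
        fs.values += np.outer(age_c, 0.03 * np.sin(8 * fs.densities))
        fit = fit_fosr(fs, build_design_matrix(cov))
        assert fit.p_overall_ < 0.001
        assert fit.p_covariates_["age"] < 0.001

    def test_null_rejection_rate_near_nominal(self):
        # truly constant coefficient functions: size of the constancy test
        rejections = 0
        done, seed = 0, 0
        while done < 100:
            try:
                fit, _, _ = _fit_cohort(
                    n=60, mean_function="constant", seed=7000 + seed
                )
            except ConfigurationError:
                seed += 1
                continue
            seed += 1
            done += 1
            rejections += fit.p_overall_ < 0.05
        assert 1 <= rejections <= 11  # ~5% of 100, generous binomial band

    def test_edf_guard_raises_when_model_collapses(self):
        fit, fs, X = _fit_cohort(n=30, seed=8)
        fit.edf_residual_ = 5.0  # force the degenerate condition
        with pytest.raises(ConfigurationError, match="edf"):
            fit._overall_test()


class TestR2Family:
    def test_pure_noise_has_near_zero_functional_r2(self):
        vals = []
        for seed in range(10):
            fit, _, _ = _fit_cohort(n=80, mean_function="constant", seed=200 + seed)
            vals.append(fit.functional_r2_)
        assert abs(np.mean(vals)) < 0.05

    def test_noiseless_single_covariate_approaches_one(self):
        rng = np.random.default_rng(9)
        n, m = 40, 15
        d = np.linspace(0.01, 0.3, m)
        x = rng.normal(size=(n, 1))
        y = x @ np.ones((1, m)) * 0.5
        model = FunctionOnScalarRegression(densities=d)
        model.fit(x, y)
        assert model.functional_r2_ > 0.999

    def test_nested_rss_monotone_at_fixed_lambda(self):
        fit, fs, X = _fit_cohort(n=50, age_effect=-0.01, seed=10)
        # dropping any covariate can only increase RSS at the same lambda
        for name, rss_reduced in fit._rss_drop_.items():
            assert rss_reduced >= fit.rss_ - 1e-9

    def test_semipartial_zero_effect_near_zero_and_clamped(self):
        fit, _, _ = _fit_cohort(n=80, age_effect=-0.01, seed=11)
        # sex/handedness/distance carry no true effect
        for name in ("sex_female", "distance"):
            assert fit.semipartial_[name] < 0.05
        assert all(v >= 0 for v in fit.semipartial_.values())
        assert fit.semipartial_["age"] > 0.1


class TestBootstrap:
    def test_deterministic_given_seed(self):
        fit, _, _ = _fit_cohort(n=40, age_effect=-0.01, seed=12)
        ci1 = fit.bootstrap_ci(n_boot=100, seed=3)
        lo1 = {k: v[0].copy() for k, v in ci1.items()}
        ci2 = fit.bootstrap_ci(n_boot=100, seed=3)
        for k in ci1:
            np.testing.assert_array_equal(lo1[k], ci2[k][0])

    def test_noiseless_deterministic_response_has_collapsed_bands(self):
        rng = np.random.default_rng(13)
        n, m = 30, 12
        x = rng.normal(size=(n, 1))
        y = 1.0 + x @ np.full((1, m), 0.25)
        model = FunctionOnScalarRegression(densities=np.linspace(0.01, 0.3, m))
        model.fit(x, y)
        ci = model.bootstrap_ci(n_boot=100, seed=0)
        for name in model.coef_names_:
            lo, hi = ci[name]
            assert np.all(hi - lo < 1e-6)

    def test_minimum_bootstrap_size_enforced(self):
        fit, _, _ = _fit_cohort(n=30, seed=14)
        with pytest.raises(ConfigurationError):
            fit.bootstrap_ci(n_boot=50)

    def test_null_age_band_covers_zero(self):
        # with no true age effect the band should contain 0 almost everywhere
        coverage = []
        done, seed = 0, 0
        while done < 20:
            try:
                fit, _, _ = _fit_cohort(n=60, age_effect=0.0, seed=400 + seed)
            except ConfigurationError:
                seed += 1
                continue
            seed += 1
            done += 1
            lo, hi = fit.bootstrap_ci(n_boot=100, seed=seed)["age"]
            coverage.append(np.mean((lo <= 0) & (0 <= hi)))
        assert np.mean(coverage) >= 0.90


class TestSignificanceSummary:
    def test_requires_bootstrap_first(self):
        fit, _, _ = _fit_cohort(n=30, seed=15)
        with pytest.raises(ConfigurationError, match="bootstrap"):
            fit.significance_summary()

    def test_nonsignificant_overall_model_gates_everything(self):
        fit, _, _ = _fit_cohort(n=60, age_effect=-0.01, seed=16)
        fit.bootstrap_ci(n_boot=100, seed=1)
        fit.p_overall_ = 0.5  # force the overall gate shut
        summary = fit.significance_summary(alpha=0.001)
        assert not summary["significant"].any()

    def test_full_domain_when_alpha_one_and_strong_effect(self):
        fit, _, _ = _fit_cohort(n=80, age_effect=-0.02, seed=17)
        fit.bootstrap_ci(n_boot=100, seed=2)
        summary = fit.significance_summary(alpha=1.0)
        row = summary[summary["covariate"] == "age"].iloc[0]
        assert row["significant"] and row["direction"] == -1.0
        lo, hi = row["ranges"][0]
        d = fit.densities_
        assert lo == pytest.approx(d[0]) and row["ranges"][-1][1] == pytest.approx(d[-1])

    def test_reported_ranges_match_ci_exclusion(self):
        fit, _, _ = _fit_cohort(n=80, age_effect=-0.015, seed=18)
        fit.bootstrap_ci(n_boot=150, seed=3)
        summary = fit.significance_summary(alpha=0.001)
        row = summary[summary["covariate"] == "age"].iloc[0]
        excl = (fit.ci_lower_["age"] > 0) | (fit.ci_upper_["age"] < 0)
        gate = fit.p_overall_ < 0.001 and fit.p_covariates_["age"] < 0.001
        in_range = np.zeros(len(fit.densities_), dtype=bool)
        for lo, hi in row["ranges"]:
            in_range |= (fit.densities_ >= lo) & (fit.densities_ <= hi)
        np.testing.assert_array_equal(in_range, excl & gate)
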