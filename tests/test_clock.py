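import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import ElasticNet

from equusage.clock import (
    ClockConfig,
    ClockModel,
    apply_clock,
    evaluate_predictions,
    fit_elastic_net,
    inverse_transform_age,
    lambda_path,
    loo_predict,
    select_lambda,
    train_clock,
    transform_age,
)
from equusage.simulate import gen_ages, gen_methylation
from equusage.types import BetaMatrix, ValidationError

from conftest import make_beta, make_sheet


class TestAgeTransform:
    def test_sqrt_and_inverse_identity(self):
        assert transform_age(4.0) == pytest.approx(2.0)
        for x in (0.0, 0.15, 20.2):
            t = transform_age(x)
            back, clamped = inverse_transform_age(t)
            assert back == pytest.approx(x, abs=1e-12)
            assert not clamped

    def test_negative_prediction_clamps_with_flag(self):
        years, clamped = inverse_transform_age(np.array([-0.1, 1.0]))
        assert years[0] == 0.0 and clamped[0]
        assert years[1] == pytest.approx(1.0) and not clamped[1]

    def test_domain_error_below_offset(self):
        with pytest.raises(ValidationError):
            transform_age(-0.5, "sqrt", 0.2)

    def test_identity_mode_passthrough(self):
        assert transform_age(3.7, "identity") == 3.7


class TestElasticNet:
    def test_large_lambda_gives_null_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        fit = fit_elastic_net(X, y, alpha=1.0, lam=1e6)
        np.testing.assert_array_equal(fit.coef, 0.0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_ridge_matches_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        lam = 0.25
        fit = fit_elastic_net(
            X, y, alpha=0.0, lam=lam, standardize=False, fit_intercept=False
        )
        oracle = np.linalg.solve(X.T @ X + 20 * lam * np.eye(5), X.T @ y)
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-6)

    def test_univariate_lasso_matches_soft_threshold(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        x = (x - x.mean()) / x.std()
        y = 0.6 * x + rng.normal(size=80) * 0.2
        lam = 0.15
        fit = fit_elastic_net(x[:, None], y, alpha=1.0, lam=lam, standardize=False)
        rho = np.mean(x * (y - y.mean()))
        cxx = np.mean(x * x)
        oracle = np.sign(rho) * max(abs(rho) - lam, 0.0) / cxx
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-8)

    def test_matches_sklearn_coordinate_descent(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 15))
        y = X[:, :3] @ np.array([1.0, -0.5, 0.25]) + rng.normal(size=40) * 0.1
        lam, alpha = 0.05, 0.7
        ours = fit_elastic_net(X, y, alpha=alpha, lam=lam, standardize=False)
        ref = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-10,
                         max_iter=100_000).fit(X, y)
        np.testing.assert_allclose(ours.coef, ref.coef_, atol=1e-6)
        assert ours.intercept == pytest.approx(ref.intercept_, abs=1e-6)

    def test_kkt_residual_small_at_solution(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        fit = fit_elastic_net(X, y, alpha=0.5, lam=0.02)
        assert fit.kkt <= 1e-6

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        alpha=st.floats(0.0, 1.0),
        lam=st.floats(1e-4, 1.0),
    )
    def test_objective_non_increasing_every_sweep(self, seed, alpha, lam):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        fit = fit_elastic_net(X, y, alpha=alpha, lam=lam, record_objective=True)
        trace = fit.objective_trace
        assert trace.size >= 1
        assert np.all(np.diff(trace) <= 1e-12)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        perm = rng.permutation(8)
        a = fit_elastic_net(X, y, alpha=0.5, lam=0.05)
        b = fit_elastic_net(X[:, perm], y, alpha=0.5, lam=0.05)
        np.testing.assert_allclose(a.coef[perm], b.coef, atol=1e-8)

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 2.5
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_elastic_net(X, y, alpha=0.5, lam=0.01)
        assert fit.coef[1] == 0.0

    def test_non_finite_input_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_elastic_net(X, np.ones(5), alpha=0.5, lam=0.1)


class TestLambdaSelection:
    def test_lambda_max_zeroes_every_weight(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 20))
        y = X[:, 0] + rng.normal(size=30) * 0.1
        lams = lambda_path(X, y, alpha=0.5)
        fit = fit_elastic_net(X, y, alpha=0.5, lam=lams[0])
        np.testing.assert_array_equal(fit.coef, 0.0)

    def test_noiseless_signal_selects_small_lambda(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10)
        sel = select_lambda(X, y, alpha=0.5, folds=5)
        assert sel.lam <= np.quantile(sel.path, 0.1)

    def test_pure_noise_keeps_model_sparse(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(30, 50))
            y = rng.normal(size=30)
            sel = select_lambda(X, y, alpha=0.5, folds=5, seed=seed)
            fit = fit_elastic_net(X, y, alpha=0.5, lam=sel.lam)
            if np.count_nonzero(fit.coef) <= 2:
                hits += 1
        assert hits >= 90

    def test_too_few_samples_for_folds(self):
        with pytest.raises(ValidationError):
            select_lambda(np.ones((3, 2)), np.ones(3), alpha=0.5, folds=5)


class TestClockTraining:
    def test_recovers_informative_sites_at_reasonable_sparsity(self, blood_cohort):
        sheet, beta, truth = blood_cohort
        model = train_clock(beta, sheet, ClockConfig(cv_folds=10))
        assert 5 <= model.n_sites <= 200
        informative = {
            s for s, role in zip(truth.site_ids, truth.role) if role == "clock_linear"
        }
        overlap = len(informative & set(model.coefficients))
        assert overlap >= 5  # picks up genuinely informative sites

    def test_refuses_tiny_cohorts(self):
        ages = np.linspace(1, 10, 5)
        beta = make_beta(np.random.default_rng(0).random((5, 20)))
        with pytest.raises(ValidationError, match="10"):
            train_clock(beta, make_sheet(ages))

    def test_missing_tissue_filter_errors(self, blood_cohort):
        sheet, beta, _ = blood_cohort
        with pytest.raises(ValidationError, match="no samples"):
            train_clock(beta, sheet, ClockConfig(tissue="biopsy"))

    def test_duplicate_profiles_warn_but_fit(self):
        rng = np.random.default_rng(9)
        ages = np.linspace(0.5, 15, 12)
        vals = rng.random((12, 30))
        vals[1] = vals[0]  # identical samples, different ages
        beta = make_beta(vals)
        with pytest.warns(UserWarning, match="duplicate"):
            model = train_clock(beta, make_sheet(ages), ClockConfig(cv_folds=4))
        assert isinstance(model, ClockModel)


class TestLOOPrediction:
    def test_noiseless_recovery_to_1e3_years(self):
        ages = gen_ages(20, 1.0, 16.0, seed=20)
        beta, _ = gen_methylation(
            ages, n_sites=60, frac_clock=10 / 60, frac_pacemaker=0.0,
            noise_sd=0.0, seed=21,
        )
        cfg = ClockConfig(cv_folds="loo", lambda_min_ratio=1e-8, n_lambdas=120)
        preds = loo_predict(beta, make_sheet(ages), cfg)
        np.testing.assert_allclose(preds.ages, ages, atol=1e-3)

    def test_duplicated_sample_predicted_near_twin(self):
        ages = gen_ages(15, 1.0, 16.0, seed=22)
        beta, _ = gen_methylation(
            ages, n_sites=60, frac_clock=10 / 60, frac_pacemaker=0.0,
            noise_sd=0.005, seed=23,
        )
        vals = np.vstack([beta.values, beta.values[0]])
        ages2 = np.append(ages, ages[0])
        preds = loo_predict(make_beta(vals), make_sheet(ages2), ClockConfig(cv_folds=5))
        assert abs(preds.ages[-1] - ages[0]) < 1.0

    def test_two_samples_insufficient(self):
        beta = make_beta(np.random.default_rng(0).random((2, 10)))
        with pytest.raises(ValidationError):
            loo_predict(beta, make_sheet([1.0, 2.0]))


class TestApplyClock:
    def test_arithmetic_of_sparse_model(self):
        model = ClockModel("sqrt", 0.0, 1.0, {"cgA": 0.5}, 0.5, 0.1)
        beta = BetaMatrix(["s0"], ["cgA"], np.array([[0.2]]))
        preds = apply_clock(model, beta)
        assert preds.ages[0] == pytest.approx(1.21)

    def test_all_sites_missing_zero_contribution(self):
        model = ClockModel("sqrt", 0.0, 1.5, {"cgA": 0.5, "cgB": -0.2}, 0.5, 0.1)
        beta = BetaMatrix(["s0", "s1"], ["cgX"], np.array([[0.2], [0.9]]))
        preds = apply_clock(model, beta, missing_policy="zero_contribution")
        np.testing.assert_allclose(preds.ages, 1.5**2)
        assert preds.n_missing_sites.tolist() == [2, 2]

    def test_error_policy_lists_missing_sites(self):
        model = ClockModel("sqrt", 0.0, 1.0, {"cgA": 0.5, "cgB": 1.0}, 0.5, 0.1)
        beta = BetaMatrix(["s0"], ["cgA"], np.array([[0.2]]))
        with pytest.raises(ValidationError, match="cgB"):
            apply_clock(model, beta, missing_policy="error")


class TestEvaluation:
    def test_perfect_and_shifted_predictions(self):
        true = np.array([1.0, 3.0, 7.0, 12.0])
        ev = evaluate_predictions(true, true)
        assert ev.pearson_r == pytest.approx(1.0) and ev.mae == 0.0
        ev2 = evaluate_predictions(true + 1, true)
        assert ev2.mae == pytest.approx(1.0) and ev2.pearson_r == pytest.approx(1.0)

    def test_median_not_mean_absolute_error(self):
        ev = evaluate_predictions([1.0, 2.0, 9.0], [1.0, 3.0, 5.0])
        assert ev.mae == pytest.approx(1.0)  # median of (0, 1, 4)

    def test_stratified_mae_at_cut_age(self):
        true = np.array([1.0, 2.0, 16.0, 20.0])
        pred = true + np.array([0.5, 0.5, 3.0, 3.0])
        ev = evaluate_predictions(pred, true, age_split=15.0)
        assert ev.mae_below_split == pytest.approx(0.5)
        assert ev.mae_at_or_above_split == pytest.approx(3.0)

    def test_zero_variance_reports_undefined_r(self):
        ev = evaluate_predictions([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert ev.pearson_r is None
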