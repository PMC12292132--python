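"""Closed-form fitting: hand-checked examples, oracle equivalence and
order/penalty monotonicity properties."""

import numpy as np
import pytest
from scipy import optimize

from fetalgrowth.defaults import REFERENCE_COEFFICIENTS, REFERENCE_R2_BY_DEGREE
from fetalgrowth.errors import (
    InvalidParameterError,
    RangeError,
    SingularDesignError,
    UndefinedStatisticError,
)
from fetalgrowth.polynomial import (
    GrowthCurveModel,
    build_design_matrix,
    coefficient_standard_errors,
    fit_ols,
    fit_ridge,
    polyval_ascending,
    r_squared,
    rmse,
    select_degree,
)
from fetalgrowth.records import Parameter


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "ages, degree, expected",
        [
            ([2, 3], 2, [[1, 2, 4], [1, 3, 9]]),
            ([5], 0, [[1]]),
            ([0, 1, 2], 1, [[1, 0], [1, 1], [1, 2]]),
        ],
    )
    def test_basis_expansion(self, ages, degree, expected):
        dm = build_design_matrix(ages, degree)
        np.testing.assert_array_equal(dm.matrix, np.asarray(expected, dtype=float))
        np.testing.assert_array_equal(dm.ages, np.asarray(ages, dtype=float))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            build_design_matrix([1.0], -1)
        with pytest.raises(InvalidParameterError):
            build_design_matrix([], 2)


class TestOls:
    def test_exact_interpolation(self):
        # y = 1 + x^2 through three points: zero residuals
        res = fit_ols(build_design_matrix([0, 1, 2], 2), [1, 2, 5])
        np.testing.assert_allclose(res.params, [1, 0, 1], atol=1e-12)
        np.testing.assert_allclose(res.resid, 0, atol=1e-12)

    def test_hand_solved_normal_equations(self):
        res = fit_ols(build_design_matrix([0, 1, 2], 1), [0, 1, 1])
        np.testing.assert_allclose(res.params, [1 / 6, 1 / 2], rtol=1e-12)

    @pytest.mark.parametrize("degree", [1, 2, 3])
    def test_noiseless_identifiability(self, degree, rng):
        theta = rng.normal(size=degree + 1)
        ages = np.linspace(0.0, 2.0, 40)  # well-conditioned span
        y = polyval_ascending(theta, ages)
        res = fit_ols(build_design_matrix(ages, degree), y)
        np.testing.assert_allclose(res.params, theta, rtol=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.rmse < 1e-9 * np.abs(y).max()

    def test_duplicate_age_is_singular(self):
        with pytest.raises(SingularDesignError, match="ridge"):
            fit_ols(build_design_matrix([7, 7, 7], 1), [1, 2, 3])


class TestRidge:
    def test_degree_zero_closed_form(self):
        # theta0 = sum(y) / (n + lambda) = 6 / 3
        res = fit_ridge(build_design_matrix([10, 20], 0), [2, 4], lam=1.0)
        assert res.params[0] == pytest.approx(2.0, rel=1e-12)

    def test_lambda_zero_reduces_to_ols(self, rng):
        ages = rng.uniform(50, 300, 30)
        y = rng.normal(size=30)
        dm = build_design_matrix(ages, 2)
        np.testing.assert_allclose(
            fit_ridge(dm, y, 0.0).params, fit_ols(dm, y).params, atol=1e-10
        )

    def test_huge_penalty_shrinks_to_zero(self):
        res = fit_ridge(build_design_matrix([1, 2, 3, 4], 1), [1, 2, 3, 4], lam=1e12)
        np.testing.assert_allclose(res.params, 0, atol=1e-6)

    def test_training_r2_nonincreasing_in_lambda(self, rng):
        ages = rng.uniform(0, 1, 60)
        y = 1 + 2 * ages + rng.normal(0, 0.3, 60)
        dm = build_design_matrix(ages, 2)
        r2s = [fit_ridge(dm, y, lam).rsquared for lam in (0.0, 0.01, 0.1, 1.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_closed_form_matches_numerical_minimizer(self, rng):
        """Closed-form solutions coincide with an independent iterative
        minimizer of the penalized cost on >= 50 random instances."""
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(8, 50))
            d = int(rng.integers(0, 4))
            lam = float(rng.choice([0.0, 0.01, 0.1, 1.0, 10.0]))
            ages = rng.uniform(0, 1, n)  # rescaled for oracle conditioning
            y = rng.normal(0, 1, n)
            dm = build_design_matrix(ages, d)
            res = fit_ridge(dm, y, lam)

            def cost(theta, Phi=dm.matrix, y=y, lam=lam):
                r = y - Phi @ theta
                return r @ r + lam * theta @ theta

            def grad(theta, Phi=dm.matrix, y=y, lam=lam):
                return 2 * (Phi.T @ (Phi @ theta - y)) + 2 * lam * theta

            opt = optimize.minimize(
                cost, np.zeros(d + 1), jac=grad, method="BFGS",
                options={"gtol": 1e-12, "maxiter": 10_000},
            )
            worst = max(worst, float(np.max(np.abs(opt.x - res.params))))
        assert worst < 1e-6


class TestFitStatistics:
    @pytest.mark.parametrize(
        "y, y_hat, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [2, 2, 2], 0.0),
            ([1, 2, 3], [1, 2, 4], 0.5),
        ],
    )
    def test_r_squared_examples(self, y, y_hat, expected):
        assert r_squared(y, y_hat) == pytest.approx(expected, abs=1e-12)

    def test_r_squared_constant_y_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_rmse_examples(self):
        assert rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5), rel=1e-12)
        assert rmse([1, 2], [1, 2]) == 0.0
        # constant residual c -> |c|
        assert rmse([5, 5, 5], [2, 2, 2]) == pytest.approx(3.0, rel=1e-12)

    def test_rmse_empty_invalid(self):
        with pytest.raises(InvalidParameterError):
            rmse([], [])


class TestCoefficientStandardErrors:
    def test_zero_residuals_give_zero_se(self):
        dm = build_design_matrix([0, 1, 2, 3], 1)
        se = coefficient_standard_errors(dm, [1, 3, 5, 7])
        np.testing.assert_allclose(se, 0, atol=1e-12)

    def test_hand_computed_ols_covariance(self):
        se = coefficient_standard_errors(build_design_matrix([0, 1, 2], 1), [0, 1, 1])
        np.testing.assert_allclose(
            se, [np.sqrt(5 / 36), np.sqrt(1 / 12)], rtol=1e-10
        )

    def test_matches_explicit_covariance_formula(self, rng):
        """SVD-based SEs agree with the textbook s^2 (Phi'Phi)^-1 inverse
        computed directly, on 20 random instances."""
        for _ in range(20):
            n = int(rng.integers(6, 30))
            d = int(rng.integers(0, 4))
            ages = rng.uniform(0, 2, n)
            y = rng.normal(size=n)
            dm = build_design_matrix(ages, d)
            theta = np.linalg.solve(dm.matrix.T @ dm.matrix, dm.matrix.T @ y)
            resid = y - dm.matrix @ theta
            s2 = resid @ resid / (n - d - 1)
            oracle = np.sqrt(
                np.diag(s2 * np.linalg.inv(dm.matrix.T @ dm.matrix))
            )
            se = coefficient_standard_errors(dm, y)
            np.testing.assert_allclose(se, oracle, rtol=1e-8, atol=1e-12)

    def test_zero_degrees_of_freedom_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_standard_errors(build_design_matrix([0, 1], 1), [1, 2])

    def test_ridge_sandwich_reduces_to_ols_at_zero(self, rng):
        ages = rng.uniform(0, 1, 25)
        y = rng.normal(size=25)
        dm = build_design_matrix(ages, 2)
        np.testing.assert_allclose(
            coefficient_standard_errors(dm, y, lam=0.0),
            coefficient_standard_errors(dm, y, lam=1e-14),
            rtol=1e-6,
        )


class TestPredict:
    def test_reference_curve_values_at_term(self):
        """Evaluating the published quadratics at day 280 reproduces the
        hand-computed means (EFW 3390.61 g, AC 33.73 cm)."""
        efw = polyval_ascending(REFERENCE_COEFFICIENTS[Parameter.EFW], 280.0)
        ac = polyval_ascending(REFERENCE_COEFFICIENTS[Parameter.AC], 280.0)
        assert efw == pytest.approx(3390.61, abs=0.005)
        assert ac == pytest.approx(33.73, abs=0.005)

    def test_zero_coefficients_predict_zero(self):
        dm = build_design_matrix([1, 2, 3], 2)
        assert polyval_ascending([0, 0, 0], 123.0) == 0.0

    def test_out_of_range_refused_without_flag(self, rng):
        ages = rng.uniform(100, 200, 20)
        res = GrowthCurveModel(rng.normal(size=20), ages, degree=1).fit()
        with pytest.raises(RangeError, match="range"):
            res.predict(500.0)
        assert np.isfinite(res.predict(500.0, extrapolate=True))


class TestDegreeSelection:
    @pytest.mark.parametrize(
        "fits, expected",
        [
            ({1: 0.9132, 2: 0.9539, 3: 0.9551}, 2),  # weight
            ({1: 0.9640, 2: 0.9732, 3: 0.9732}, 2),  # thigh length
            ({1: 0.99, 2: 0.99, 3: 0.99}, 1),  # ties favour simplicity
        ],
    )
    def test_parsimony_rule(self, fits, expected):
        assert select_degree(fits, epsilon=0.005) == expected

    def test_missing_degree_invalid(self):
        with pytest.raises(InvalidParameterError):
            select_degree({1: 0.9, 2: 0.95})

    def test_training_r2_monotone_in_degree(self, rng):
        ages = rng.uniform(80, 294, 200)
        y = polyval_ascending([1, 0.05, 1e-4], ages) + rng.normal(0, 0.5, 200)
        r2s = [
            GrowthCurveModel(y, ages, degree=d).fit().rsquared for d in (1, 2, 3)
        ]
        assert r2s[0] <= r2s[1] + 1e-12 <= r2s[2] + 2e-12

    def test_epsilon_zero_prefers_strictly_best_degree(self):
        assert select_degree({1: 0.90, 2: 0.95, 3: 0.96}, epsilon=0.0) == 3


class TestSummary:
    def test_summary_mentions_fit_quantities(self, rng):
        ages = rng.uniform(80, 294, 50)
        y = polyval_ascending([1, 0.1], ages) + rng.normal(0, 0.1, 50)
        res = GrowthCurveModel(y, ages, degree=2, lam=0.1,
                               parameter=Parameter.AC).fit()
        text = res.summary()
        assert "AC" in text and "R-squared" in text and "x^2" in text

    def test_json_round_trip_full_precision(self, tmp_path, rng):
        import json

        ages = rng.uniform(80, 294, 50)
        y = polyval_ascending([1, 0.1], ages) + rng.normal(0, 0.1, 50)
        res = GrowthCurveModel(y, ages, degree=2, parameter=Parameter.FL).fit()
        path = tmp_path / "model.json"
        res.to_json(path)
        d = json.loads(path.read_text())
        np.testing.assert_array_equal(d["coefficients"], res.params)
        np.testing.assert_array_equal(d["coefficient_se"], res.bse)
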