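"""Polynomial surrogate of the t_g surface: features, fit, scan, costs."""

import numpy as np
import pytest

from stridetime import (
    GridSpec,
    PolynomialSurrogate,
    TimingPair,
    fit_surrogate,
    grid_sensitivity,
    operation_count,
    order_scan,
    polynomial_features,
    predict_tg,
    solve_grid,
    solve_tg,
)
from stridetime.surrogate import (
    ExtrapolationWarning,
    FeasibilityError,
    SurrogateFitError,
    n_terms,
)


class TestFeatures:
    @pytest.mark.parametrize("order, expected", [(1, 3), (3, 10), (8, 45), (14, 120)])
    def test_term_counts(self, order, expected):
        X = np.array([[0.2, 0.2]])
        A, powers = polynomial_features(X, order)
        assert A.shape == (1, expected)
        assert powers.shape == (expected, 2)
        assert n_terms(order) == expected

    def test_graded_lexicographic_order(self):
        _, powers = polynomial_features(np.array([[0.2, 0.3]]), 2)
        assert powers.tolist() == [[0, 0], [1, 0], [0, 1], [2, 0], [1, 1], [0, 2]]

    def test_values_are_monomials(self):
        A, powers = polynomial_features(np.array([[2.0, 3.0]]), 3)
        expected = [2.0**i * 3.0**j for i, j in powers]
        np.testing.assert_allclose(A[0], expected)

    def test_rejects_order_below_one(self):
        with pytest.raises(ValueError):
            polynomial_features(np.array([[0.2, 0.2]]), 0)


class TestPolynomialSurrogateEstimator:
    def test_recovers_exact_low_order_polynomial(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.05, 0.5, (50, 2))
        y = 0.01 + 0.3 * X[:, 0] - 0.2 * X[:, 1] + 0.5 * X[:, 0] * X[:, 1] + 0.1 * X[:, 1] ** 2
        model = PolynomialSurrogate(order=2).fit(X, y)
        np.testing.assert_allclose(model.predict(X, check_feasible=False), y, atol=1e-12)

    def test_constant_and_zero_models(self):
        model = PolynomialSurrogate(order=1)
        X = np.array([[0.2, 0.2], [0.3, 0.3], [0.25, 0.31]])
        model.fit(X, np.zeros(3))
        np.testing.assert_allclose(model.predict(X, check_feasible=False), 0.0, atol=1e-15)
        model.coef_ = np.array([0.042, 0.0, 0.0])
        np.testing.assert_allclose(model.predict(X, check_feasible=False), 0.042)

    def test_structural_rank_deficiency_raises(self):
        X = np.tile([[0.2, 0.2]], (30, 1))  # one distinct point
        with pytest.raises(SurrogateFitError, match="distinct points"):
            PolynomialSurrogate(order=2).fit(X, np.full(30, 0.043))

    def test_too_few_points_raises(self):
        X = np.array([[0.2, 0.2], [0.3, 0.3], [0.25, 0.31]])
        with pytest.raises(SurrogateFitError, match="needs"):
            PolynomialSurrogate(order=2).fit(X, np.zeros(3))

    def test_infeasible_prediction_rejected(self, default_grid):
        model = fit_surrogate(default_grid, order=3)
        with pytest.raises(FeasibilityError):
            model.predict(np.array([[0.2, 0.1]]))

    def test_extrapolation_warns(self, default_grid):
        model = fit_surrogate(default_grid, order=3)
        with pytest.warns(ExtrapolationWarning):
            model.predict(np.array([[0.6, 0.6]]))

    def test_sklearn_get_set_params(self):
        model = PolynomialSurrogate(order=5)
        assert model.get_params() == {"order": 5}
        assert model.set_params(order=3).order == 3


class TestFitOnGrid:
    def test_metadata_recorded(self, default_grid):
        model = fit_surrogate(default_grid, order=8)
        assert model.seed_ == 42
        assert model.train_fraction_ == 0.85
        assert model.grid_spec_ == default_grid.spec
        assert 0 < model.rmse_test_ < 0.001
        assert model.r_squared_test_ > 0.999

    def test_deterministic_given_seed(self, default_grid):
        a = fit_surrogate(default_grid, order=6, seed=11)
        b = fit_surrogate(default_grid, order=6, seed=11)
        assert np.array_equal(a.coef_, b.coef_)

    def test_agrees_with_direct_solver_at_typical_step(self, default_grid):
        model = fit_surrogate(default_grid, order=8)
        pair = TimingPair(0.2, 0.2)
        assert predict_tg(model, pair) == pytest.approx(solve_tg(pair), abs=0.001)

    def test_large_test_errors_confined_to_boundary(self, default_grid):
        # only a handful of held-out points err by more than 2 ms, and all of
        # them sit hard against the feasibility boundary where the surface
        # has a square-root-like edge that polynomials track poorly
        from stridetime import boundary_ratio_analytic
        from stridetime._split import split_indices

        model = fit_surrogate(default_grid, order=8)
        X, y = default_grid.solved_points()
        _, test = split_indices(len(y), 0.85, 42)
        err = np.abs(model.predict(X[test], check_feasible=False) - y[test])
        big = err > 0.002
        assert big.sum() <= 0.01 * len(test)
        ratios = X[test][big][:, 1] / X[test][big][:, 0]
        assert np.all(ratios < boundary_ratio_analytic() + 0.01)

    def test_reconstruction_error_is_twice_tg_error(self, default_grid):
        # t_c = t_ce + 2 t_g makes the t_c RMSE exactly double the t_g RMSE
        model = fit_surrogate(default_grid, order=8)
        X, y = default_grid.solved_points()
        pred = model.predict(X, check_feasible=False)
        rmse_tg = np.sqrt(np.mean((pred - y) ** 2))
        tc_true = X[:, 0] + 2 * y
        tc_pred = X[:, 0] + 2 * pred
        rmse_tc = np.sqrt(np.mean((tc_pred - tc_true) ** 2))
        assert rmse_tc == pytest.approx(2 * rmse_tg, rel=1e-12)


class TestOrderScan:
    def test_rmse_decreases_broadly_with_order(self, default_grid):
        scan = order_scan(default_grid)
        rmse_ms = np.array(scan.rmse) * 1e3
        assert rmse_ms[0] > 10  # linear fit is far off
        assert rmse_ms[scan.orders.index(3)] == pytest.approx(2.5, abs=0.5)
        assert rmse_ms[scan.orders.index(14)] < 0.5
        assert scan.selected_order == min(
            n for n, r in zip(scan.orders, scan.rmse) if r < scan.threshold
        )

    def test_infinite_threshold_selects_order_one(self, default_grid):
        scan = order_scan(default_grid, threshold=np.inf)
        assert scan.selected_order == 1

    def test_unreachable_threshold_raises(self, default_grid):
        with pytest.raises(SurrogateFitError, match="best achieved"):
            order_scan(default_grid, orders=[1, 2], threshold=1e-9)

    def test_frame_output(self, default_grid):
        scan = order_scan(default_grid, orders=[1, 2, 3], threshold=np.inf)
        df = scan.to_frame()
        assert list(df.columns) == ["order", "rmse_ms", "r_squared"]
        assert len(df) == 3


class TestOperationCount:
    @pytest.mark.parametrize("order, total", [(1, 4), (3, 25), (8, 130)])
    def test_totals(self, order, total):
        assert operation_count(order).total == total

    def test_components(self):
        c = operation_count(8)
        assert (c.features, c.multiplications, c.additions) == (42, 44, 44)

    def test_rejects_order_below_one(self):
        with pytest.raises(ValueError):
            operation_count(0)


class TestGridSensitivity:
    def test_small_grids_build_and_fit(self):
        df = grid_sensitivity(axis_sizes=[6, 10], orders=[1, 2, 3])
        assert set(df["n_points"]) == {36, 100}
        assert (df["rmse_ms"] > 0).all()
        # coarser grids have fewer training points, so high orders are skipped
        assert df[df["axis_size"] == 6]["order"].max() <= 3

    def test_solved_fraction_roughly_grid_independent(self):
        fractions = []
        for m in (10, 20):
            spacing = (0.505 - 0.0025) / (m - 1)
            grid = solve_grid(GridSpec(start=0.0025, stop=0.505, spacing=spacing))
            fractions.append(grid.n_solved / grid.n_total)
        assert abs(fractions[0] - fractions[1]) < 0.05
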