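import numpy as np
import pandas as pd
import pytest

from esgeo.kriging import (
    CrossValidationReport,
    cross_validate,
    error_metrics,
    krige_grid,
    ordinary_kriging_predict,
    rank_models,
)
from esgeo.synthetic import RegionSpec
from esgeo.variogram import VariogramModel

MODEL = VariogramModel(nugget=0.0, sill=1.0, range_=4000.0)
MODEL_NUGGET = VariogramModel(nugget=0.3, sill=1.0, range_=4000.0)


@pytest.fixture
def training(rng):
    loc = rng.uniform(0, 10_000, size=(30, 2))
    vals = rng.normal(size=30)
    return loc, vals


class TestOrdinaryKriging:
    def test_exact_interpolation_with_zero_nugget(self, training):
        loc, vals = training
        preds = ordinary_kriging_predict(loc, vals, MODEL, loc)
        for i, p in enumerate(preds):
            assert p.value == pytest.approx(vals[i], abs=1e-8)
            assert p.variance == pytest.approx(0.0, abs=1e-8)
            assert p.weights[i] == pytest.approx(1.0, abs=1e-8)

    def test_weights_sum_to_one(self, training, rng):
        loc, vals = training
        targets = rng.uniform(-2000, 12_000, size=(100, 2))
        for p in ordinary_kriging_predict(loc, vals, MODEL_NUGGET, targets):
            assert np.sum(p.weights) == pytest.approx(1.0, abs=1e-10)
            assert p.variance >= 0.0

    def test_matches_independent_dense_solve(self):
        """Three fixed points, one target: compare to a standalone linear solve."""
        loc = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1500.0]])
        vals = np.array([2.0, 5.0, -1.0])
        target = np.array([[400.0, 600.0]])
        model = VariogramModel(nugget=0.2, sill=1.5, range_=2500.0)

        def gamma(h):
            if h == 0:
                return 0.0
            hr = min(h / 2500.0, 1.0)
            return 0.2 + 1.3 * (1.5 * hr - 0.5 * hr**3)

        A = np.zeros((4, 4))
        for i in range(3):
            for j in range(3):
                A[i, j] = gamma(float(np.hypot(*(loc[i] - loc[j]))))
        A[3, :3] = 1.0
        A[:3, 3] = 1.0
        b = np.array([gamma(float(np.hypot(*(target[0] - loc[i])))) for i in range(3)] + [1.0])
        sol = np.linalg.solve(A, b)
        expected_value = sol[:3] @ vals
        expected_var = sol[:3] @ b[:3] + sol[3]

        p = ordinary_kriging_predict(loc, vals, model, target)[0]
        assert p.value == pytest.approx(expected_value, abs=1e-10)
        assert p.variance == pytest.approx(expected_var, abs=1e-10)
        np.testing.assert_allclose(p.weights, sol[:3], atol=1e-10)

    def test_unbiasedness_constraint_is_active(self, training):
        """Dropping the constraint row changes the prediction (simple kriging differs)."""
        loc, vals = training
        target = np.array([[5000.0, 5000.0]])
        p = ordinary_kriging_predict(loc, vals, MODEL_NUGGET, target)[0]
        from scipy.spatial.distance import cdist, pdist, squareform

        G = MODEL_NUGGET.semivariance(squareform(pdist(loc)))
        g0 = MODEL_NUGGET.semivariance(cdist(target, loc))[0]
        lam_free = np.linalg.solve(G + 1e-12 * np.eye(len(loc)), g0)
        assert abs(lam_free @ vals - p.value) > 1e-6

    def test_nearest_k_neighborhood(self, training):
        loc, vals = training
        target = np.array([[5000.0, 5000.0]])
        p_all = ordinary_kriging_predict(loc, vals, MODEL_NUGGET, target, neighborhood_size=len(loc))[0]
        p_global = ordinary_kriging_predict(loc, vals, MODEL_NUGGET, target)[0]
        assert p_all.value == pytest.approx(p_global.value, abs=1e-9)
        p_k = ordinary_kriging_predict(loc, vals, MODEL_NUGGET, target, neighborhood_size=8)[0]
        assert len(p_k.weights) == 8
        assert np.sum(p_k.weights) == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_training_points_raise(self):
        loc = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]])
        with pytest.raises(np.linalg.LinAlgError, match="duplicate"):
            ordinary_kriging_predict(loc, [1.0, 2.0, 3.0], MODEL, [[5.0, 5.0]])

    def test_too_few_training_points_raise(self):
        with pytest.raises(ValueError, match="at least 3"):
            ordinary_kriging_predict([[0, 0], [1, 1]], [0.0, 1.0], MODEL, [[2, 2]])


class TestKrigeGrid:
    REGION = RegionSpec(origin_x=0.0, origin_y=0.0, width_m=10_000.0, height_m=10_000.0)

    def test_grid_dimensions(self, training):
        loc, vals = training
        surf = krige_grid(loc, vals, MODEL_NUGGET, self.REGION, cell_size_m=500.0)
        assert (surf.n_rows, surf.n_cols) == (20, 20)

    def test_constant_training_values_give_constant_surface(self, training):
        loc, _ = training
        surf = krige_grid(loc, np.full(len(loc), 7.25), MODEL_NUGGET, self.REGION, 1000.0)
        np.testing.assert_allclose(surf.values, 7.25, atol=1e-9)

    def test_cells_equal_direct_point_prediction(self, training):
        loc, vals = training
        surf = krige_grid(loc, vals, MODEL_NUGGET, self.REGION, cell_size_m=2500.0)
        # row 0 is northernmost; cell centers at offset + 0.5 cell
        for r, c in [(0, 0), (3, 2), (1, 3)]:
            x = 0.0 + (c + 0.5) * 2500.0
            y = 10_000.0 - (r + 0.5) * 2500.0
            p = ordinary_kriging_predict(loc, vals, MODEL_NUGGET, [[x, y]])[0]
            assert surf.values[r, c] == pytest.approx(p.value, abs=1e-10)

    def test_back_transform_is_lognormal_mean(self, training):
        loc, vals = training
        raw = krige_grid(loc, vals, MODEL_NUGGET, self.REGION, 2500.0)
        bt = krige_grid(loc, vals, MODEL_NUGGET, self.REGION, 2500.0, back_transform=True)
        assert bt.transform == "raw"
        p = ordinary_kriging_predict(
            loc, vals, MODEL_NUGGET, [[1250.0, 10_000.0 - 1250.0]]
        )[0]
        assert bt.values[0, 0] == pytest.approx(np.exp(p.value + 0.5 * p.variance), rel=1e-9)
        assert raw.values[0, 0] == pytest.approx(p.value, abs=1e-9)


class TestCrossValidation:
    def test_error_metrics_worked_example(self):
        me, rmse = error_metrics([1.0, 2.0, 3.0], [1.5, 2.0, 2.5])
        assert me == pytest.approx(0.0, abs=1e-15)
        assert rmse == pytest.approx(0.40825, abs=1e-5)

    def test_zero_residuals(self):
        me, rmse = error_metrics([1.0, 2.0], [1.0, 2.0])
        assert me == 0.0 and rmse == 0.0

    def test_holdout_split_sizes(self, small_survey):
        _, table, model = small_survey
        cv = cross_validate(table, "es", model, mode="holdout",
                            holdout_fraction=0.10, seed=4, transform="log")
        assert cv.n_train == round(len(table) * 0.9)
        assert cv.n_train + cv.n_test == len(table)
        assert cv.rmse >= abs(cv.me)
        assert cv.seed == 4

    def test_holdout_is_seed_deterministic(self, small_survey):
        _, table, model = small_survey
        a = cross_validate(table, "es", model, seed=9, transform="log")
        b = cross_validate(table, "es", model, seed=9, transform="log")
        np.testing.assert_array_equal(a.residuals, b.residuals)

    def test_loo_produces_one_residual_per_plot(self, small_survey):
        _, table, model = small_survey
        sub = table.iloc[:15]
        cv = cross_validate(sub, "es", model, mode="loo", transform="log")
        assert cv.mode == "loo"
        assert len(cv.residuals) == 15
        assert cv.n_test == 15

    def test_unknown_mode_raises(self, small_survey):
        _, table, model = small_survey
        with pytest.raises(ValueError, match="mode"):
            cross_validate(table, "es", model, mode="bootstrap")


class TestModelRanking:
    def test_smaller_rmse_wins_with_me_tiebreak(self):
        def report(me, rmse):
            return CrossValidationReport(me=me, rmse=rmse, n_train=9, n_test=1,
                                         residuals=np.zeros(1), mode="holdout", seed=0)

        reports = {
            "worse": report(0.01, 0.9),
            "best": report(0.05, 0.4),
            "biased_tie": report(-0.3, 0.4),
        }
        ranked = rank_models(reports)
        assert ranked[0] == "best"  # RMSE ties broken toward |ME| = 0
        assert ranked == ["best", "biased_tie", "worse"]
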