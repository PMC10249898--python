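import numpy as np
import pytest

from esgeo.variogram import (
    VariogramModel,
    average_nearest_neighbor_distance,
    classify_spatial_dependence,
    empirical_semivariogram,
    fit_spherical_model,
    lag_structure,
)


def brute_force_semivariogram(loc, vals, lag_step, n_lags, max_dist):
    """Independent oracle: exhaustive enumeration of unordered pairs."""
    n = len(loc)
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(loc[i] - loc[j])))
            if d == 0 or d > max_dist:
                continue
            k = int(d // lag_step)
            if k >= n_lags:
                continue
            sums[k] += (vals[i] - vals[j]) ** 2
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, 0.5 * sums / np.maximum(counts, 1), np.nan)
    return gamma, counts


class TestAverageNearestNeighbor:
    def test_two_points(self):
        assert average_nearest_neighbor_distance([[0, 0], [100, 0]]) == pytest.approx(100.0)

    def test_unit_square_corners(self):
        corners = [[0, 0], [1, 0], [0, 1], [1, 1]]
        assert average_nearest_neighbor_distance(corners) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        loc = rng.uniform(0, 1000, size=(50, 2))
        expected = np.mean(
            [
                min(np.hypot(*(loc[i] - loc[j])) for j in range(50) if j != i)
                for i in range(50)
            ]
        )
        assert average_nearest_neighbor_distance(loc) == pytest.approx(expected, rel=1e-12)

    def test_duplicate_coordinates_warn(self):
        with pytest.warns(UserWarning, match="share coordinates"):
            average_nearest_neighbor_distance([[0, 0], [0, 0], [5, 5]])

    def test_single_point_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            average_nearest_neighbor_distance([[1, 2]])


class TestLagStructure:
    def test_half_max_rule(self):
        # collinear points every 1000 m out to 30 km: ANN=1000, max=30000
        loc = np.column_stack([np.arange(0, 30_001, 1000.0), np.zeros(31)])
        lags = lag_structure(loc)
        assert lags.lag_step == pytest.approx(1000.0)
        assert lags.max_dist == pytest.approx(30_000.0)
        assert lags.n_lags == 15

    def test_override_honored(self):
        loc = np.column_stack([np.arange(0, 30_001, 1000.0), np.zeros(31)])
        assert lag_structure(loc, n_lags=15).n_lags == 15
        assert lag_structure(loc, n_lags=7).n_lags == 7

    def test_max_dist_matches_brute_force(self, rng):
        loc = rng.uniform(0, 5000, size=(40, 2))
        expected = max(
            np.hypot(*(loc[i] - loc[j])) for i in range(40) for j in range(i + 1, 40)
        )
        assert lag_structure(loc).max_dist == pytest.approx(expected, rel=1e-12)

    def test_collocated_points_raise(self):
        with pytest.raises(ValueError, match="collocated"):
            lag_structure([[1, 1], [1, 1], [1, 1]])


class TestEmpiricalSemivariogram:
    def test_hand_enumerated_collinear_example(self):
        loc = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        vals = np.array([0.0, 1.0, 3.0])
        emp = empirical_semivariogram(loc, vals, lag_step=1.0, n_lags=3, max_dist=3.0)
        # pairs at distance 1: (0,1) diff 1, (1,2) diff 2 -> gamma = (1+4)/(2*2)
        assert emp.gamma[1] == pytest.approx(1.25)
        # pair at distance 2: (0,2) diff 3 -> gamma = 9/2
        assert emp.gamma[2] == pytest.approx(4.5)
        assert emp.counts[0] == 0 and np.isnan(emp.gamma[0])

    def test_constant_field_is_zero(self, rng):
        loc = rng.uniform(0, 100, size=(20, 2))
        emp = empirical_semivariogram(loc, np.full(20, 3.3), 10.0, 10, 150.0)
        assert np.all(emp.gamma[emp.populated()] == 0.0)

    def test_linear_drift_identity(self):
        # values equal to the x coordinate on an integer line: within the bin
        # [k, k+1) every pair sits exactly at distance k, so gamma = k^2 / 2
        x = np.arange(10.0)
        loc = np.column_stack([x, np.zeros_like(x)])
        emp = empirical_semivariogram(loc, x, lag_step=1.0, n_lags=9, max_dist=9.0)
        for k in range(1, 9):
            assert emp.gamma[k] == pytest.approx(k**2 / 2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        loc = rng.uniform(0, 1000, size=(n, 2))
        vals = rng.normal(size=n)
        lag_step = float(rng.uniform(50, 200))
        n_lags = int(rng.integers(4, 12))
        max_dist = lag_step * n_lags * float(rng.uniform(0.6, 1.2))
        emp = empirical_semivariogram(loc, vals, lag_step, n_lags, max_dist)
        gamma, counts = brute_force_semivariogram(loc, vals, lag_step, n_lags, max_dist)
        np.testing.assert_array_equal(emp.counts, counts)
        np.testing.assert_allclose(emp.gamma, gamma, atol=1e-12, equal_nan=True)

    def test_binning_is_pure_under_more_lags(self, rng):
        loc = rng.uniform(0, 500, size=(25, 2))
        vals = rng.normal(size=25)
        a = empirical_semivariogram(loc, vals, 50.0, 6, 800.0)
        b = empirical_semivariogram(loc, vals, 50.0, 12, 800.0)
        np.testing.assert_allclose(a.gamma, b.gamma[:6], atol=1e-15, equal_nan=True)

    def test_all_pairs_beyond_max_dist_raise(self):
        loc = np.array([[0.0, 0.0], [1000.0, 0.0]])
        with pytest.raises(ValueError, match="empty"):
            empirical_semivariogram(loc, [0.0, 1.0], 10.0, 5, 50.0)


class TestFitSphericalModel:
    def _exact_empirical(self, model, lag_step=500.0, n_lags=12):
        from esgeo.variogram import EmpiricalVariogram

        lag_mid = (np.arange(n_lags) + 0.5) * lag_step
        return EmpiricalVariogram(
            lag_step=lag_step,
            n_lags=n_lags,
            max_dist=lag_step * n_lags,
            lag_mid=lag_mid,
            gamma=np.asarray(model.semivariance(lag_mid)),
            counts=np.full(n_lags, 50),
        )

    def test_noiseless_self_consistency(self):
        truth = VariogramModel(nugget=0.1, sill=1.0, range_=5000.0)
        emp = self._exact_empirical(truth)
        fit, diag = fit_spherical_model(emp)
        assert fit.nugget == pytest.approx(0.1, abs=1e-6)
        assert fit.sill == pytest.approx(1.0, abs=1e-6)
        assert fit.range_ == pytest.approx(5000.0, abs=1e-2)
        assert diag.converged

    def test_pure_nugget_limit(self):
        from esgeo.variogram import EmpiricalVariogram

        n_lags = 8
        lag_mid = (np.arange(n_lags) + 0.5) * 100.0
        emp = EmpiricalVariogram(100.0, n_lags, 800.0, lag_mid,
                                 np.full(n_lags, 0.7), np.full(n_lags, 30))
        fit, _ = fit_spherical_model(emp)
        assert fit.nugget_ratio >= 0.99

    def test_sill_within_bounds_of_sample_variance(self, small_survey):
        _, table, _ = small_survey
        loc = table[["x", "y"]].to_numpy()
        logv = np.log(table["es"].to_numpy())
        lags = lag_structure(loc)
        emp = empirical_semivariogram(loc, logv, lags.lag_step, lags.n_lags, lags.max_dist)
        fit, _ = fit_spherical_model(emp)
        var = logv.var()
        assert 0.25 * var <= fit.sill <= 4.0 * var

    def test_too_few_lags_raise(self):
        truth = VariogramModel(nugget=0.1, sill=1.0, range_=5000.0)
        emp = self._exact_empirical(truth, n_lags=3)
        with pytest.raises(ValueError, match="4 populated lags"):
            fit_spherical_model(emp)


class TestSpatialDependenceClass:
    @pytest.mark.parametrize(
        "ratio_pct,label",
        [
            (21.31, "strong"),  # carbon storage
            (30.48, "moderate"),  # avoided surface runoff
            (60.33, "moderate"),  # pollution removal
            (80.0, "weak"),
            (25.0, "moderate"),  # boundary: 25-75 inclusive is moderate
            (75.0, "moderate"),
        ],
    )
    def test_threshold_labels(self, ratio_pct, label):
        model = VariogramModel(nugget=ratio_pct / 100.0, sill=1.0, range_=1000.0)
        cls = classify_spatial_dependence(model)
        assert cls.label == label
        assert cls.nugget_ratio_percent == pytest.approx(ratio_pct)

    def test_zero_sill_raises(self):
        model = VariogramModel(nugget=0.0, sill=0.0, range_=100.0)
        with pytest.raises(ValueError, match="sill"):
            classify_spatial_dependence(model)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            VariogramModel(nugget=2.0, sill=1.0, range_=100.0)
        with pytest.raises(ValueError):
            VariogramModel(nugget=0.1, sill=1.0, range_=0.0)
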