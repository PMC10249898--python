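"""Ordinary kriging prediction, grid interpolation and cross-validation.

Ordinary kriging predicts Z(x0) = sum_i lambda_i Z(x_i) with weights that
minimize the prediction variance subject to the unbiasedness constraint
sum lambda_i = 1, solved from the fitted semivariogram via the augmented
system

    [ Gamma  1 ] [ lambda ]   [ gamma0 ]
    [ 1^T    0 ] [ mu     ] = [ 1      ],

where Gamma_ij = gamma(d_ij) between training points (0 on the diagonal,
so data points are honoured exactly) and gamma0 is the semivariance from
each training point to the target.  The kriging variance is
lambda^T gamma0 + mu.

Cross-validation follows the usual protocols: a seeded 90/10 hold-out
split (240 plots -> 216 training, 24 validation) or leave-one-out, scored
by the mean error ME = mean(x_i - x_hat_i) and the root-mean-square error
RMSE = sqrt(mean((x_i - x_hat_i)^2)).  ME near 0 with a small RMSE marks
the better model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .synthetic import RegionSpec
from .variogram import VariogramModel

__all__ = [
    "KrigingPrediction",
    "RasterSurface",
    "CrossValidationReport",
    "ordinary_kriging_predict",
    "krige_grid",
    "cross_validate",
    "error_metrics",
    "rank_models",
]


@dataclass(frozen=True)
class KrigingPrediction:
    location: tuple[float, float]
    value: float
    variance: float  # kriging variance, >= 0 up to numerical tolerance
    weights: np.ndarray  # lambda_i, one per neighbor used
    neighbor_indices: np.ndarray  # indices into the training set


@dataclass(frozen=True)
class RasterSurface:
    """Row-major grid, row 0 = northernmost row (ESRI ASCII convention)."""

    origin_x: float  # xllcorner
    origin_y: float  # yllcorner
    cell_size_m: float
    values: np.ndarray  # (n_rows, n_cols); NaN marks nodata internally
    nodata: float = -9999.0
    transform: str = "log"  # scale tag: "log" | "raw"

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CrossValidationReport:
    me: float
    rmse: float
    n_train: int
    n_test: int
    residuals: np.ndarray  # x_i - x_hat_i, observed minus predicted
    mode: str  # "holdout" | "loo"
    seed: int | None


def _solve_ok_system(train_loc, train_vals, model, target_loc):
    """Dense global-neighborhood OK solve; one LU factorization, many targets."""
    n = len(train_loc)
    d = squareform(pdist(train_loc))
    if n > 1:
        offdiag = d[np.triu_indices(n, k=1)]
        if np.any(offdiag == 0):
            i, j = np.argwhere((d == 0) & ~np.eye(n, dtype=bool))[0]
            raise np.linalg.LinAlgError(
                f"duplicate training locations at indices {i} and {j} "
                "make the kriging system singular"
            )
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.semivariance(d)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    lu = lu_factor(A)

    d0 = cdist(target_loc, train_loc)
    B = np.empty((n + 1, len(target_loc)))
    B[:n, :] = model.semivariance(d0).T
    B[n, :] = 1.0
    sol = lu_solve(lu, B)
    lam = sol[:n, :]  # (n, n_targets)
    mu = sol[n, :]
    preds = lam.T @ train_vals
    variances = np.einsum("ij,ij->j", lam, B[:n, :]) + mu
    return preds, variances, lam


def ordinary_kriging_predict(
    train_locations,
    train_values,
    model: VariogramModel,
    target_locations,
    neighborhood_size: int | None = None,
) -> list[KrigingPrediction]:
    """Ordinary-kriging prediction at each target location.

    With ``neighborhood_size=None`` (default) every training point enters
    each prediction (global neighborhood); otherwise only the k nearest
    training points do.  With a zero nugget, predicting at a training
    location returns the observation exactly with variance 0.
    """
    train_loc = np.asarray(train_locations, dtype=float)
    train_vals = np.asarray(train_values, dtype=float)
    target_loc = np.atleast_2d(np.asarray(target_locations, dtype=float))
    if len(train_loc) < 3:
        raise ValueError(f"need at least 3 training points, got {len(train_loc)}")
    if len(train_loc) != len(train_vals):
        raise ValueError("training locations and values must be aligned")
    n = len(train_loc)
    if neighborhood_size is not None and not (1 <= neighborhood_size <= n):
        raise ValueError(
            f"neighborhood_size={neighborhood_size} must be in [1, {n}]"
        )

    out: list[KrigingPrediction] = []
    if neighborhood_size is None or neighborhood_size >= n:
        preds, variances, lam = _solve_ok_system(train_loc, train_vals, model, target_loc)
        idx = np.arange(n)
        for t in range(len(target_loc)):
            out.append(
                KrigingPrediction(
                    location=(float(target_loc[t, 0]), float(target_loc[t, 1])),
                    value=float(preds[t]),
                    variance=float(max(variances[t], 0.0)),
                    weights=lam[:, t].copy(),
                    neighbor_indices=idx,
                )
            )
        return out

    tree = cKDTree(train_loc)
    _, nbr = tree.query(target_loc, k=neighborhood_size)
    nbr = np.atleast_2d(nbr)
    for t in range(len(target_loc)):
        idx = np.sort(nbr[t])
        preds, variances, lam = _solve_ok_system(
            train_loc[idx], train_vals[idx], model, target_loc[t : t + 1]
        )
        out.append(
            KrigingPrediction(
                location=(float(target_loc[t, 0]), float(target_loc[t, 1])),
                value=float(preds[0]),
                variance=float(max(variances[0], 0.0)),
                weights=lam[:, 0].copy(),
                neighbor_indices=idx,
            )
        )
    return out


def krige_grid(
    train_locations,
    train_values,
    model: VariogramModel,
    region: RegionSpec,
    cell_size_m: float,
    neighborhood_size: int | None = None,
    transform: str = "log",
    back_transform: bool = False,
) -> RasterSurface:
    """Interpolate onto a regular grid of cell centers covering the region.

    With ``back_transform=True`` the surface holds the lognormal
    back-transform exp(z_hat + sigma_k^2 / 2) of log-scale predictions.
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    n_cols = int(np.ceil(region.width_m / cell_size_m))
    n_rows = int(np.ceil(region.height_m / cell_size_m))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("empty grid")
    xs = region.origin_x + (np.arange(n_cols) + 0.5) * cell_size_m
    # row 0 is the northernmost row
    ys = region.origin_y + region.height_m - (np.arange(n_rows) + 0.5) * cell_size_m
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    preds = ordinary_kriging_predict(
        train_locations, train_values, model, targets, neighborhood_size
    )
    values = np.array([p.value for p in preds]).reshape(n_rows, n_cols)
    if back_transform:
        variances = np.array([p.variance for p in preds]).reshape(n_rows, n_cols)
        values = np.exp(values + 0.5 * variances)
        transform = "raw"
    return RasterSurface(
        origin_x=region.origin_x,
        origin_y=region.origin_y,
        cell_size_m=float(cell_size_m),
        values=values,
        transform=transform,
    )


def error_metrics(observed, predicted) -> tuple[float, float]:
    """Mean error and root-mean-square error of predictions.

    ME = mean(x_i - x_hat_i) measures systematic bias; RMSE =
    sqrt(mean((x_i - x_hat_i)^2)) the overall accuracy.  RMSE >= |ME| always.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be non-empty and aligned")
    resid = obs - pred
    return float(resid.mean()), float(np.sqrt(np.mean(resid**2)))


def cross_validate(
    table: pd.DataFrame,
    service: str,
    model: VariogramModel,
    mode: str = "holdout",
    holdout_fraction: float = 0.10,
    seed: int = 0,
    transform: str = "none",
    neighborhood_size: int | None = None,
) -> CrossValidationReport:
    """Hold-out or leave-one-out cross-validation of ordinary kriging.

    ``table`` needs columns ``x``, ``y`` and ``service``.  The hold-out
    split is seeded and uniform with n_train = round(n * (1 - fraction));
    leave-one-out removes each plot in turn.  Residuals are observed minus
    predicted, on the (possibly log-transformed) working scale.
    """
    loc = table[["x", "y"]].to_numpy(dtype=float)
    vals = table[service].to_numpy(dtype=float)
    n = len(vals)
    if n < 10:
        raise ValueError(f"need at least 10 plots for cross-validation, got {n}")
    if transform == "log":
        if np.any(vals <= 0):
            raise ValueError("log transform requires strictly positive values")
        vals = np.log(vals)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    if mode == "holdout":
        if not (0.0 < holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        n_train = int(round(n * (1.0 - holdout_fraction)))
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        preds = ordinary_kriging_predict(
            loc[train_idx], vals[train_idx], model, loc[test_idx], neighborhood_size
        )
        residuals = vals[test_idx] - np.array([p.value for p in preds])
        report_seed: int | None = seed
        n_test = n - n_train
    elif mode == "loo":
        residuals = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            pred = ordinary_kriging_predict(
                loc[mask], vals[mask], model, loc[i : i + 1], neighborhood_size
            )[0]
            residuals[i] = vals[i] - pred.value
            mask[i] = True
        n_train, n_test = n - 1, n
        report_seed = None
    else:
        raise ValueError(f"unknown cross-validation mode {mode!r}")

    me, rmse = error_metrics(residuals, np.zeros_like(residuals))
    return CrossValidationReport(
        me=me,
        rmse=rmse,
        n_train=n_train,
        n_test=len(residuals) if mode == "holdout" else n,
        residuals=residuals,
        mode=mode,
        seed=report_seed,
    )


def rank_models(reports: dict[str, CrossValidationReport]) -> list[str]:
    """Order candidate models best-first: smaller RMSE wins, |ME| closer to 0 breaks ties."""
    return sorted(reports, key=lambda k: (reports[k].rmse, abs(reports[k].me)))
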