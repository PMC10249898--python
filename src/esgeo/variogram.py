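"""Empirical semivariograms, spherical model fitting and spatial-dependence classification.

The workflow mirrors standard geostatistical practice for irregularly
sampled plot data: the lag step is taken from the average nearest-neighbor
distance, the number of lag bins spans about half the maximum pairwise
distance, the experimental semivariogram uses the Matheron estimator

    gamma(h) = 1 / (2 N(h)) * sum_{pairs at lag h} (x_i - x_j)^2,

and a spherical model is fitted by weighted least squares.  The fitted
nugget-to-sill ratio Co/C classifies the strength of spatial dependence
(<25% strong, 25-75% moderate, >75% weak).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "SpatialDependenceClass",
    "LagStructure",
    "FitDiagnostics",
    "average_nearest_neighbor_distance",
    "lag_structure",
    "empirical_semivariogram",
    "fit_spherical_model",
    "classify_spatial_dependence",
]


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram model.

    Parameters
    ----------
    nugget : float
        Co, the semivariance at the y-intercept (measurement error plus
        micro-scale variation).  Variance units.
    sill : float
        C, the total sill (plateau of the variogram).  Variance units.
    range_ : float
        a, the distance in metres beyond which pairs are effectively
        uncorrelated.
    """

    nugget: float
    sill: float
    range_: float
    form: str = "spherical"

    def __post_init__(self) -> None:
        if self.form != "spherical":
            raise ValueError(f"unsupported variogram form: {self.form!r}")
        if not (0.0 <= self.nugget <= self.sill):
            raise ValueError(
                f"require 0 <= nugget <= sill, got Co={self.nugget}, C={self.sill}"
            )
        if self.range_ <= 0:
            raise ValueError(f"range must be positive, got {self.range_}")

    @property
    def partial_sill(self) -> float:
        """C - Co, the spatially structured part of the variance."""
        return self.sill - self.nugget

    @property
    def nugget_ratio(self) -> float:
        """Co/C in [0, 1]; requires C > 0."""
        if self.sill == 0:
            raise ValueError("nugget ratio undefined for zero sill")
        return self.nugget / self.sill

    def semivariance(self, h):
        """Model semivariance gamma(h); gamma(0) = 0, jumps to Co as h -> 0+."""
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / self.range_, 1.0)
        gamma = self.nugget + self.partial_sill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h > 0, gamma, 0.0)

    def covariance(self, h):
        """Structured covariance C(h) = (C - Co) * (1 - 1.5 h/a + 0.5 (h/a)^3).

        The nugget is *not* included: it is treated as independent
        per-observation noise (variance Co at h = 0 exactly).
        """
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / self.range_, 1.0)
        return self.partial_sill * (1.0 - 1.5 * hr + 0.5 * hr**3)


@dataclass(frozen=True)
class SpatialDependenceClass:
    nugget_ratio_percent: float
    label: str  # strong | moderate | weak


@dataclass(frozen=True)
class LagStructure:
    lag_step: float
    n_lags: int
    max_dist: float


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned experimental semivariogram.

    ``gamma`` is NaN for bins with no pairs; ``counts`` holds N(h) per bin.
    Bins are left-closed right-open intervals [k*lag_step, (k+1)*lag_step),
    unordered pairs counted once, pairs beyond ``max_dist`` excluded.
    """

    lag_step: float
    n_lags: int
    max_dist: float
    lag_mid: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray

    def populated(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class FitDiagnostics:
    weighted_sse: float
    n_starts: int
    converged: bool
    weights: str = "npairs"
    start_params: tuple = field(default=())


def _as_locations(locations) -> np.ndarray:
    loc = np.asarray(locations, dtype=float)
    if loc.ndim != 2 or loc.shape[1] != 2:
        raise ValueError(f"locations must be (n, 2), got shape {loc.shape}")
    return loc


def average_nearest_neighbor_distance(locations) -> float:
    """Mean over points of the Euclidean distance to the nearest other point."""
    loc = _as_locations(locations)
    if len(loc) < 2:
        raise ValueError(f"need at least 2 points, got {len(loc)}")
    tree = cKDTree(loc)
    dist, _ = tree.query(loc, k=2)
    nn = dist[:, 1]
    if np.any(nn == 0):
        warnings.warn(
            f"{int(np.sum(nn == 0))} points share coordinates with another "
            "point; zero distances contribute to the average",
            stacklevel=2,
        )
    return float(nn.mean())


def lag_structure(locations, n_lags: int | None = None) -> LagStructure:
    """Lag step, bin count and maximum distance for the semivariogram.

    The lag step is the average nearest-neighbor distance (so every bin has
    at least a few pairs); the bins together span about half the maximum
    pairwise distance: n_lags = round(max_dist / 2 / lag_step), unless
    overridden.
    """
    loc = _as_locations(locations)
    if len(loc) < 2:
        raise ValueError("need at least 2 points")
    max_dist = float(pdist(loc).max())
    if max_dist == 0:
        raise ValueError("all points are collocated; lag structure undefined")
    step = average_nearest_neighbor_distance(loc)
    if step == 0:
        raise ValueError("average nearest-neighbor distance is zero")
    if n_lags is None:
        n_lags = int(round(max_dist / 2.0 / step))
    if n_lags < 1:
        raise ValueError(f"n_lags must be >= 1, got {n_lags}")
    return LagStructure(lag_step=step, n_lags=int(n_lags), max_dist=max_dist)


def empirical_semivariogram(
    locations, values, lag_step: float, n_lags: int, max_dist: float | None = None
) -> EmpiricalVariogram:
    """Matheron estimator of the semivariogram, binned by pair separation."""
    loc = _as_locations(locations)
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(loc):
        raise ValueError("locations and values must be aligned")
    if lag_step <= 0 or n_lags < 1:
        raise ValueError("lag parameters must be positive")
    if max_dist is None:
        max_dist = lag_step * n_lags

    d = pdist(loc)
    sqdiff = pdist(vals[:, None], metric="sqeuclidean")
    keep = (d > 0) & (d <= max_dist)
    d, sqdiff = d[keep], sqdiff[keep]
    bins_all = np.floor(d / lag_step).astype(np.intp)
    inside = bins_all < n_lags  # bins are right-open; beyond the last edge dropped
    bins = bins_all[inside]

    counts = np.bincount(bins, minlength=n_lags)[:n_lags]
    sums = np.bincount(bins, weights=sqdiff[inside], minlength=n_lags)[:n_lags]
    if counts.sum() == 0:
        raise ValueError("no pairs within max_dist; empirical variogram is empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = 0.5 * sums / counts
    gamma = np.where(counts > 0, gamma, np.nan)
    lag_mid = (np.arange(n_lags) + 0.5) * lag_step
    return EmpiricalVariogram(
        lag_step=float(lag_step),
        n_lags=int(n_lags),
        max_dist=float(max_dist),
        lag_mid=lag_mid,
        gamma=gamma,
        counts=counts,
    )


def _spherical(h, nugget, psill, rng):
    hr = np.minimum(h / rng, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


def fit_spherical_model(
    emp: EmpiricalVariogram, weights: str = "npairs"
) -> tuple[VariogramModel, FitDiagnostics]:
    """Fit a spherical model to the experimental semivariogram by WLS.

    Parameters are (Co, C - Co, a) with bounds Co >= 0, C - Co >= 0 and
    0 < a <= max_dist.  Weights are N(h) per lag (``"npairs"``, default) or
    Cressie's N(h)/gamma_model(h)^2 (``"cressie"``, applied iteratively with
    the model from the previous pass).  A fixed grid of starting points makes
    the multi-start optimization deterministic.
    """
    ok = emp.populated()
    h = emp.lag_mid[ok]
    g = emp.gamma[ok]
    n = emp.counts[ok].astype(float)
    if len(h) < 4:
        raise ValueError(f"need >= 4 populated lags to fit, got {len(h)}")
    if weights not in ("npairs", "cressie"):
        raise ValueError(f"unknown weighting scheme {weights!r}")

    gmax = float(np.max(g))
    scale = gmax if gmax > 0 else 1.0
    hmax = float(emp.max_dist)

    def residuals(theta, w):
        nugget, psill, rng = theta
        return np.sqrt(w) * (_spherical(h, nugget, psill, rng) - g)

    starts = []
    for a0 in (0.15, 0.3, 0.5, 0.75, 1.0):
        for co0 in (0.0, 0.3):
            starts.append((co0 * scale, max(scale - co0 * scale, 1e-8 * scale), a0 * hmax))
    # pure-nugget start for flat variograms
    starts.append((scale, 1e-8 * scale, 0.5 * hmax))

    lb = np.array([0.0, 0.0, 1e-6 * hmax])
    ub = np.array([np.inf, np.inf, hmax])
    best = None
    best_sse = np.inf
    best_start = None
    for start in starts:
        w = n.copy()
        theta = np.clip(np.asarray(start, dtype=float), lb, ub)
        try:
            # Cressie weights depend on the model: iterate a few passes.
            n_pass = 3 if weights == "cressie" else 1
            for _ in range(n_pass):
                sol = least_squares(
                    residuals, theta, args=(w,), bounds=(lb, ub),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                theta = sol.x
                if weights == "cressie":
                    gm = np.maximum(_spherical(h, *theta), 1e-12 * scale)
                    w = n / gm**2
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best_sse * (1.0 - 1e-12):
            best, best_sse, best_start = sol, sse, start

    if best is None:
        raise RuntimeError("spherical variogram fit failed to converge from any start")

    nugget, psill, rng = best.x
    model = VariogramModel(nugget=float(nugget), sill=float(nugget + psill), range_=float(rng))
    diag = FitDiagnostics(
        weighted_sse=best_sse,
        n_starts=len(starts),
        converged=bool(best.success),
        weights=weights,
        start_params=tuple(best_start),
    )
    return model, diag


def classify_spatial_dependence(model: VariogramModel) -> SpatialDependenceClass:
    """Classify spatial dependence from the nugget ratio Co/C (percent).

    <25% strong, 25-75% moderate, >75% weak.
    """
    if model.sill <= 0:
        raise ValueError("cannot classify a model with zero sill")
    pct = 100.0 * model.nugget_ratio
    if pct < 25.0:
        label = "strong"
    elif pct <= 75.0:
        label = "moderate"
    else:
        label = "weak"
    return SpatialDependenceClass(nugget_ratio_percent=pct, label=label)
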