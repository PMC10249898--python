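"""Distance-band spatial weights and Getis-Ord Gi* hot/cold-spot detection.

The local statistic

    Gi*(d) = sum_j W_ij(d) X_j / sum_j X_j

compares the value sum inside a point's distance band to the global sum;
its z-score, computed from the standard randomization moments

    E[Gi*]   = W_i / n,                         W_i = sum_j W_ij
    Var[Gi*] = W_i (n - W_i) / (n^2 (n - 1)) * (S / Xbar)^2,

flags statistically significant clusters of high values (hot spots, z > 0)
and of low values (cold spots, z < 0) at the 90/95/99% levels
(|z| >= 1.65 / 1.96 / 2.58).  The star convention includes the point itself
in its own neighborhood (W_ii = 1).

Gi* assumes nonnegative values; inputs with nonpositive entries (for
instance log-transformed services) are shifted to be positive first, with
the shift recorded.  The z-score is invariant to such shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "HotspotResult",
    "distance_band_weights",
    "getis_ord_gi_star",
    "gi_star_on_surface",
    "classify_hot_cold",
    "distance_threshold_sweep",
]

#: |z| thresholds for the three significance levels, strongest first.
Z_THRESHOLDS = ((2.58, "99"), (1.96, "95"), (1.65, "90"))


@dataclass(frozen=True)
class SpatialWeights:
    """Symmetric binary distance-band weights with per-point neighbor lists."""

    distance_band: float
    include_self: bool
    neighbors: tuple[np.ndarray, ...]  # neighbor indices per point (self included if set)

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def counts(self) -> np.ndarray:
        """W_i = number of neighbors of each point (self counted when included)."""
        return np.array([len(nb) for nb in self.neighbors])


@dataclass(frozen=True)
class HotspotResult:
    g_star: np.ndarray  # Gi*(d) per point
    expected: np.ndarray  # E[Gi*]
    variance: np.ndarray  # Var[Gi*]
    z: np.ndarray
    category: np.ndarray  # hot99 .. cold99 / not_significant
    distance_band: float
    value_shift: float  # amount added to make values positive (0 if none)
    clipped_variance: bool  # True if a marginally negative variance was clipped at 0


def distance_band_weights(locations, d: float, include_self: bool = True) -> SpatialWeights:
    """Binary weights W_ij = 1 iff distance(i, j) <= d (plus W_ii when included)."""
    loc = np.asarray(locations, dtype=float)
    if loc.ndim != 2 or len(loc) < 2:
        raise ValueError("need at least 2 points")
    if d <= 0:
        raise ValueError(f"distance band must be positive, got {d}")
    tree = cKDTree(loc)
    pairs = tree.query_ball_point(loc, r=d)
    neighbors = []
    isolated = []
    for i, nb in enumerate(pairs):
        nb = np.array(sorted(nb), dtype=np.intp)
        if not include_self:
            nb = nb[nb != i]
        if len(nb) - (1 if include_self else 0) == 0:
            isolated.append(i)
        neighbors.append(nb)
    if isolated:
        warnings.warn(
            f"{len(isolated)} points have no neighbors within {d} m "
            f"(indices {isolated[:10]}{'...' if len(isolated) > 10 else ''})",
            stacklevel=2,
        )
    return SpatialWeights(
        distance_band=float(d), include_self=include_self, neighbors=tuple(neighbors)
    )


def getis_ord_gi_star(values, weights: SpatialWeights) -> HotspotResult:
    """Gi* statistic, randomization moments, z-score and hot/cold category per point."""
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise ValueError("values must be aligned with the weights")
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.all(x == x[0]):
        raise ValueError("zero variance of values: Gi* is degenerate (no spatial signal)")

    shift = 0.0
    if x.min() <= 0:
        # Gi* is defined for nonnegative values; the z-score is shift-invariant
        shift = float(-x.min() + 0.01 * (x.max() - x.min()))
        x = x + shift

    total = x.sum()
    xbar = x.mean()
    s = np.sqrt(np.mean(x**2) - xbar**2)
    wi = weights.counts().astype(float)
    local_sum = np.array([x[nb].sum() for nb in weights.neighbors])

    g = local_sum / total
    expected = wi / n
    var = wi * (n - wi) / (n**2 * (n - 1)) * (s / xbar) ** 2
    clipped = bool(np.any(var < 0))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (g - expected) / np.sqrt(var), 0.0)
    return HotspotResult(
        g_star=g,
        expected=expected,
        variance=var,
        z=z,
        category=classify_hot_cold(z),
        distance_band=weights.distance_band,
        value_shift=shift,
        clipped_variance=clipped,
    )


def classify_hot_cold(z) -> np.ndarray:
    """Map z-scores to {hot99, hot95, hot90, not_significant, cold90, cold95, cold99}."""
    z = np.asarray(z, dtype=float)
    cats = np.full(z.shape, "not_significant", dtype=object)
    for thr, level in Z_THRESHOLDS:
        cats[(z >= thr) & (cats == "not_significant")] = f"hot{level}"
        cats[(z <= -thr) & (cats == "not_significant")] = f"cold{level}"
    return cats.astype(str)


def gi_star_on_surface(surface, d: float, include_self: bool = True):
    """Run Gi* on the cells of a kriged raster surface.

    Nodata (NaN) cells are excluded.  Returns the :class:`HotspotResult`
    over the valid cells and a category grid aligned with the surface
    (nodata cells marked ``"nodata"``).
    """
    vals = surface.values
    rows, cols = np.nonzero(np.isfinite(vals))
    if len(rows) < 3:
        raise ValueError("surface has fewer than 3 valid cells")
    # cell centers; row 0 is the northernmost row
    x = surface.origin_x + (cols + 0.5) * surface.cell_size_m
    y = surface.origin_y + (vals.shape[0] - rows - 0.5) * surface.cell_size_m
    loc = np.column_stack([x, y])
    weights = distance_band_weights(loc, d, include_self=include_self)
    res = getis_ord_gi_star(vals[rows, cols], weights)
    grid = np.full(vals.shape, "nodata", dtype=object)
    grid[rows, cols] = res.category
    return res, grid.astype(str)


def distance_threshold_sweep(
    values, locations, d_list, include_self: bool = True
) -> pd.DataFrame:
    """Run Gi* at each distance band; summarize significant-point counts per band.

    ``d_list`` must be strictly increasing.  Returns one row per band with
    counts of hot/cold points at each level.
    """
    d_arr = np.asarray(d_list, dtype=float)
    if len(d_arr) == 0 or np.any(np.diff(d_arr) <= 0):
        raise ValueError("d_list must be non-empty and strictly increasing")
    rows = []
    for d in d_arr:
        w = distance_band_weights(locations, d, include_self=include_self)
        res = getis_ord_gi_star(values, w)
        cat = pd.Series(res.category)
        rows.append(
            {
                "distance_band": d,
                "n_hot99": int((cat == "hot99").sum()),
                "n_hot95": int(cat.isin(["hot99", "hot95"]).sum()),
                "n_hot90": int(cat.isin(["hot99", "hot95", "hot90"]).sum()),
                "n_cold99": int((cat == "cold99").sum()),
                "n_cold95": int(cat.isin(["cold99", "cold95"]).sum()),
                "n_cold90": int(cat.isin(["cold99", "cold95", "cold90"]).sum()),
                "n_significant_95": int((np.abs(res.z) >= 1.96).sum()),
            }
        )
    return pd.DataFrame(rows)
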