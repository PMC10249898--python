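"""Calibration and recovery experiments on synthetic plot surveys.

These functions run the method-validation experiments the package is
checked against: simulate plot surveys with known ground truth, then
measure how well each stage recovers it —

* variogram parameter recovery and spatial-dependence classification,
* cross-validation mean-error calibration of ordinary kriging,
* Gi* hot-spot size (false-positive rate on exchangeable noise) and power
  (detection of an implanted high-value cluster),
* geographical-detector q recovery for strong and null zonal drivers.

Every experiment is deterministic given its seed; per-replicate seeds are
spawned from one :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodetector import factor_q, jenks_breaks
from .hotspot import distance_band_weights, getis_ord_gi_star
from .kriging import cross_validate
from .synthetic import (
    DriverSpec,
    RegionSpec,
    SamplingDesign,
    SyntheticFieldSpec,
    grid_random_sample,
    simulate_driver_layers,
    simulate_es_field,
)
from .variogram import (
    VariogramModel,
    average_nearest_neighbor_distance,
    classify_spatial_dependence,
    empirical_semivariogram,
    fit_spherical_model,
    lag_structure,
)

__all__ = [
    "STUDY_REGION",
    "STUDY_MODEL",
    "simulate_study",
    "variogram_recovery",
    "me_calibration",
    "gi_star_null_calibration",
    "gi_star_cluster_recovery",
    "driver_recovery",
]

#: Study-scale region: 30 km x 35 km (~1050 km^2).
STUDY_REGION = RegionSpec(origin_x=0.0, origin_y=0.0, width_m=30_000.0, height_m=35_000.0)

#: Ground-truth log-scale model of the recovery experiments:
#: nugget 0.2, sill 1.0 (ratio 20% -> "strong"), range 8 km.
STUDY_MODEL = VariogramModel(nugget=0.2, sill=1.0, range_=8000.0)

#: Raster-net cell size that fits 240 one-per-cell plots into the region
#: after 20% cell exclusion (12 x 14 = 168 cells would not at 2500 m).
STUDY_CELL_M = 1750.0


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_study(
    seed: int,
    n: int = 240,
    model: VariogramModel = STUDY_MODEL,
    region: RegionSpec = STUDY_REGION,
    mean_log: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic survey: grid-random plots and the log-scale field values."""
    s_sample, s_field = _child_seeds(seed, 2)
    design = SamplingDesign(
        cell_size_m=STUDY_CELL_M, n_target=n, exclusion_fraction=0.2, seed=s_sample
    )
    locations = grid_random_sample(region, design)
    values = simulate_es_field(
        locations, SyntheticFieldSpec(model=model, mean_log=mean_log, seed=s_field)
    )
    return locations, np.log(values)


def variogram_recovery(n_seeds: int = 20, seed: int = 0) -> pd.DataFrame:
    """Fit the spherical model to ``n_seeds`` simulated surveys.

    Returns one row per replicate with the fitted (Co, C, a), the
    nugget-ratio classification and the true label for comparison.
    """
    true_label = classify_spatial_dependence(STUDY_MODEL).label
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_seeds)):
        loc, logv = simulate_study(s)
        lags = lag_structure(loc)
        emp = empirical_semivariogram(loc, logv, lags.lag_step, lags.n_lags, lags.max_dist)
        model, _ = fit_spherical_model(emp)
        cls = classify_spatial_dependence(model)
        rows.append(
            {
                "replicate": rep,
                "nugget_Co": model.nugget,
                "sill_C": model.sill,
                "range_a_m": model.range_,
                "nugget_ratio_percent": cls.nugget_ratio_percent,
                "label": cls.label,
                "true_label": true_label,
            }
        )
    return pd.DataFrame(rows)


def me_calibration(
    n_seeds: int = 20, seed: int = 0, holdout_fraction: float = 0.10
) -> pd.DataFrame:
    """Hold-out cross-validation ME/RMSE on correctly specified simulations.

    Kriging uses the true generating model, so the mean error measures pure
    calibration: it should scatter around 0 well within the field's
    standard deviation.
    """
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_seeds)):
        loc, logv = simulate_study(s)
        table = pd.DataFrame({"x": loc[:, 0], "y": loc[:, 1], "es_log": logv})
        cv = cross_validate(
            table, "es_log", STUDY_MODEL,
            mode="holdout", holdout_fraction=holdout_fraction, seed=s,
        )
        rows.append(
            {"replicate": rep, "ME": cv.me, "RMSE": cv.rmse,
             "n_train": cv.n_train, "n_test": cv.n_test,
             "field_sd": float(np.std(logv))}
        )
    return pd.DataFrame(rows)


def _study_band(locations) -> float:
    # default hot-spot band: twice the average nearest-neighbor distance
    return 2.0 * average_nearest_neighbor_distance(locations)


def gi_star_null_calibration(n_seeds: int = 20, n: int = 240, seed: int = 0) -> pd.DataFrame:
    """Fraction of |z| > 1.96 points when values are exchangeable noise.

    Under the null of no clustering the z-scores are approximately standard
    normal, so the fraction should sit near the nominal 5%.
    """
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_seeds)):
        s_loc, s_val = _child_seeds(s, 2)
        design = SamplingDesign(
            cell_size_m=STUDY_CELL_M, n_target=n, exclusion_fraction=0.2, seed=s_loc
        )
        loc = grid_random_sample(STUDY_REGION, design)
        values = np.random.default_rng(s_val).standard_normal(n)
        w = distance_band_weights(loc, _study_band(loc))
        res = getis_ord_gi_star(values, w)
        rows.append(
            {"replicate": rep, "frac_significant_95": float(np.mean(np.abs(res.z) >= 1.96))}
        )
    return pd.DataFrame(rows)


def gi_star_cluster_recovery(
    n_seeds: int = 20, n: int = 240, cluster_size: int = 8, effect_sd: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection of an implanted high-value cluster.

    A cluster of ``cluster_size`` mutually nearest plots gets its noise
    values raised by ``effect_sd`` standard deviations; the experiment
    counts how many cluster members come out hot at the 95% level.
    """
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_seeds)):
        s_loc, s_val, s_pick = _child_seeds(s, 3)
        design = SamplingDesign(
            cell_size_m=STUDY_CELL_M, n_target=n, exclusion_fraction=0.2, seed=s_loc
        )
        loc = grid_random_sample(STUDY_REGION, design)
        values = np.random.default_rng(s_val).standard_normal(n)
        # cluster: a random anchor plot and its nearest neighbors
        anchor = int(np.random.default_rng(s_pick).integers(n))
        d = np.hypot(loc[:, 0] - loc[anchor, 0], loc[:, 1] - loc[anchor, 1])
        members = np.argsort(d)[:cluster_size]
        values[members] += effect_sd
        w = distance_band_weights(loc, _study_band(loc))
        res = getis_ord_gi_star(values, w)
        hot = np.abs(res.z[members]) >= 1.96
        hot &= res.z[members] > 0
        rows.append(
            {"replicate": rep, "n_hot95_in_cluster": int(hot.sum()),
             "cluster_size": cluster_size}
        )
    return pd.DataFrame(rows)


def driver_recovery(
    n_seeds: int = 20,
    zone_effect_sd: float = 1.5,
    noise_sd: float = 0.4,
    n_zones: int = 5,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Factor-detector q of a synthetic zonal driver against its own field.

    With ``zone_effect_sd`` well above ``noise_sd`` the Jenks-discretized
    covariate should explain most of the field's variance (high q); with
    ``zone_effect_sd = 0`` it is pure noise and q should be near 0 with a
    non-significant p.
    """
    rows = []
    for rep, s in enumerate(_child_seeds(seed, n_seeds)):
        s_study, s_drv = _child_seeds(s, 2)
        loc, logv = simulate_study(s_study)
        spec = DriverSpec(
            n_zones=n_zones, zone_effect_sd=zone_effect_sd, noise_sd=noise_sd,
            seed=s_drv, name="driver",
        )
        cols = simulate_driver_layers(
            loc, logv, spec,
            x_min=STUDY_REGION.origin_x,
            x_max=STUDY_REGION.origin_x + STUDY_REGION.width_m,
        )
        res = factor_q(logv, jenks_breaks(cols["driver"], k))
        rows.append({"replicate": rep, "q": res.q, "p": res.p})
    return pd.DataFrame(rows)
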