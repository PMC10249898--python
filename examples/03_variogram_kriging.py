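"""Semivariogram fitting, spatial-dependence classification, kriging and CV.

The lag step comes from the average nearest-neighbor distance and the bins
span half the maximum pairwise distance.  A spherical model is fitted by
weighted least squares; Co/C classifies the dependence strength; ordinary
kriging is cross-validated with the 90/10 hold-out protocol (ME and RMSE).
"""

import numpy as np
import pandas as pd

from esgeo import (
    classify_spatial_dependence,
    cross_validate,
    empirical_semivariogram,
    fit_spherical_model,
    krige_grid,
    lag_structure,
)
from esgeo.experiments import STUDY_REGION, simulate_study

loc, logv = simulate_study(seed=5)  # truth: Co=0.2, C=1.0, a=8000 m
lags = lag_structure(loc)
print(f"lag step {lags.lag_step:.0f} m, {lags.n_lags} lags, max distance {lags.max_dist:.0f} m")

emp = empirical_semivariogram(loc, logv, lags.lag_step, lags.n_lags, lags.max_dist)
model, _ = fit_spherical_model(emp)
cls = classify_spatial_dependence(model)
print(f"fitted: Co={model.nugget:.3f}  C={model.sill:.3f}  a={model.range_:.0f} m")
print(f"Co/C = {cls.nugget_ratio_percent:.2f}% -> {cls.label} spatial dependence")

table = pd.DataFrame({"x": loc[:, 0], "y": loc[:, 1], "es_log": logv})
cv = cross_validate(table, "es_log", model, mode="holdout", holdout_fraction=0.10, seed=5)
print(f"hold-out CV: {cv.n_train} train / {cv.n_test} test, "
      f"ME = {cv.me:.4f}, RMSE = {cv.rmse:.4f}")
# ME near 0 means the interpolation is unbiased; RMSE is on the log scale

surface = krige_grid(loc, logv, model, STUDY_REGION, cell_size_m=1000)
print(f"kriged surface: {surface.n_rows} x {surface.n_cols} cells, "
      f"value range [{np.nanmin(surface.values):.2f}, {np.nanmax(surface.values):.2f}] (log scale)")
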