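# esgeo

Geostatistical analysis of plot-level urban-forest ecosystem services.

Field surveys of urban forests quantify services — carbon storage (kg),
carbon sequestration (kg/yr), avoided surface runoff (m³/yr), air-pollution
removal (g/yr) — on a few hundred sample plots, and then ask two spatial
questions: *how do these services vary across the city* (interpolation,
hot spots) and *what drives that variation* (socio-economic stratification).
`esgeo` implements that workflow end to end for plot tables with projected
planar coordinates, together with a synthetic survey generator with known
ground truth, so every stage can be validated by recovery experiments.

## What it computes

* **Composite ES score** — Min-Max normalization
  X′ = (X − X_min)/(X_max − X_min) per service, equal-weight sum,
  renormalized to [0, 1]; with skewness/Pearson-kurtosis diagnostics for
  the log transform used by kriging.
* **Semivariogram & spatial dependence** — Matheron estimator
  γ(h) = (1/2N(h)) Σ (x_i − x_j)², lag step from the average
  nearest-neighbor distance, bins spanning half the maximum pairwise
  distance; spherical model γ(h) = Co + (C−Co)(1.5h/a − 0.5(h/a)³) fitted
  by weighted least squares; nugget ratio Co/C classified as strong
  (<25%), moderate (25–75%) or weak (>75%) spatial dependence.
* **Ordinary kriging** — Ẑ(x₀) = Σ λᵢZ(xᵢ) with Σ λᵢ = 1, point and grid
  prediction with kriging variance, plus 90/10 hold-out and leave-one-out
  cross-validation scored by ME and RMSE.
* **Getis-Ord Gi\*** — distance-band weights, Gi\* = Σⱼ W_ij X_j / Σⱼ X_j,
  z-scores from the standard randomization moments, hot/cold categories at
  the 90/95/99% levels, and distance-threshold sweeps.
* **Geographical detector** — Jenks natural-breaks discretization, factor
  q = 1 − Σ N_m σ_m² / (N σ²) with its noncentral-F significance test, and
  the five-class interaction detector on pairwise cross-classifications.
* **Synthetic surveys** — grid-random sampling (one plot per raster cell),
  lognormal fields with spherical spatial covariance, and zonal driver
  layers with tunable explanatory power.

## Worked example

```python
import pandas as pd
from esgeo import (lag_structure, empirical_semivariogram, fit_spherical_model,
                   classify_spatial_dependence, cross_validate)
from esgeo.experiments import simulate_study

loc, logv = simulate_study(seed=5)          # 240 plots, truth Co=0.2, C=1.0, a=8000 m
lags = lag_structure(loc)
emp = empirical_semivariogram(loc, logv, lags.lag_step, lags.n_lags, lags.max_dist)
model, _ = fit_spherical_model(emp)
cls = classify_spatial_dependence(model)
table = pd.DataFrame({"x": loc[:, 0], "y": loc[:, 1], "es_log": logv})
cv = cross_validate(table, "es_log", model, holdout_fraction=0.10, seed=5)
```

printed via `python examples/03_variogram_kriging.py`:

```
lag step 1254 m, 18 lags, max distance 43931 m
fitted: Co=0.082  C=1.143  a=7649 m
Co/C = 7.20% -> strong spatial dependence
hold-out CV: 216 train / 24 test, ME = -0.0253, RMSE = 0.7597
```

The lag step is the survey's average nearest-neighbor distance; the fitted
range (7649 m) recovers the generating 8000 m; the nugget ratio classifies
the field as strongly spatially dependent; and the 240 plots split into 216
interpolation and 24 validation points, with a mean error near zero (the
interpolation is unbiased) on the log scale.

The `examples/` directory holds one short script per capability
(simulation, composite, variogram/kriging, hot spots, geodetector, full
pipeline), and `esgeo run --seed 21` executes the whole chain from the
command line, writing plot tables, variogram reports, kriged surfaces
(ESRI ASCII), hotspot tables, geodetector tables and a hashed run manifest.

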