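# Methods

This note documents the statistical procedures `esgeo` implements, the
defaults and their rationale, what the synthetic generator does and does
not emulate, and the numerical choices made where the design was open.

## Data model

The universal currency is a plot table: unique plot ids, projected planar
coordinates in metres (x east, y north; no CRS handling), one nonnegative
column per ecosystem service, and optional driver columns. All file
formats are plain text: CSV tables, ESRI ASCII grids for rasters, YAML
configuration, JSON manifests.

## Composite ecosystem-service score

Services come in incommensurable units, so each named service is Min-Max
normalized, X′ = (X − X_min)/(X_max − X_min); the normalized columns are
summed with equal weights (configurable) and the sum is Min-Max normalized
again. The second normalization forces the composite to attain both 0 and
1, and makes it invariant to positive affine rescaling of any input. A
constant column is a hard error rather than a silent zero column, because
it would otherwise contribute nothing while appearing weighted.

Normality diagnostics report moment skewness g₁ = m₃/m₂^1.5 and Pearson
kurtosis m₄/m₂² (normal reference 3, not 0). The Pearson convention is
used because the dependence classification literature this pipeline
follows reports kurtosis values clustering around 3.

Two value scales deliberately coexist: compositing operates on raw service
magnitudes, while variogram fitting and kriging operate on log-transformed
values (lognormal-like services are approximately Gaussian only after the
log). Both paths are explicit in the configuration.

## Semivariogram estimation and fitting

* Lag step: the average nearest-neighbor distance, so each lag bin holds
  at least a few pairs under irregular sampling.
* Number of lags: round(max pairwise distance / 2 / lag step) — the binned
  domain spans about half the maximum distance; overridable.
* Estimator: Matheron, γ(h) = (1/2N(h)) Σ (x_i − x_j)², with unordered
  pairs binned into left-closed right-open intervals [k·step, (k+1)·step);
  empty bins carry NaN and are excluded from fitting.
* Model: spherical only, γ(h) = Co + (C−Co)(1.5h/a − 0.5(h/a)³) for h ≤ a,
  γ = C beyond the range. Exponential/Gaussian forms are intentionally not
  implemented; the constructor rejects other forms explicitly.
* Fit: weighted least squares with N(h) weights (Cressie's N(h)/γ_model²
  available as an option, applied over three reweighting passes).
  Parameters (Co, C−Co, a) are bounded nonnegative with a ≤ max distance,
  optimized by bounded trust-region least squares from a fixed grid of 11
  starting points — deterministic, no RNG. On noiseless spherical input the
  truth is recovered to ~1e-6.
* Classification: nugget ratio 100·Co/C < 25% strong, 25–75% moderate
  (boundaries inclusive), > 75% weak.

At n = 240 plots the nugget ratio estimate is genuinely noisy: over
repeated simulations with a true ratio of 20% its spread is roughly ±12
percentage points, so individual replicates routinely cross the 25%
boundary. Recovery experiments therefore check that the fitted class stays
on the strong/moderate side of the spectrum rather than demanding an exact
label match at a boundary-adjacent truth.

## Ordinary kriging

The OK system uses model semivariances between training points with zeros
on the diagonal, augmented with the unbiasedness row/column; the Lagrange
solution yields weights (Σλ = 1 to machine precision), prediction, and
kriging variance λᵀγ₀ + μ (clipped at 0 against round-off). With a zero
nugget, prediction at a training point returns the observation with zero
variance.

The default neighborhood is global (all training points, one LU
factorization shared across targets) — exact and fast for surveys of a few
hundred plots; a nearest-k neighborhood is available for larger problems.
Duplicate training locations make the system singular and raise an error
naming the offending pair.

Predictions are reported on the working (log) scale by default; the
lognormal back-transform exp(ẑ + σ²_k/2) is available behind a flag, since
interpolated-map scales are a presentation choice, not part of the
estimator.

Cross-validation: seeded uniform hold-out with n_train = round(n(1−f))
(240 plots at f = 0.10 give exactly 216/24), or leave-one-out. Residuals
are observed minus predicted; ME = mean residual, RMSE = root mean square
residual (so RMSE ≥ |ME| always). Candidate models rank by smaller RMSE
with |ME| toward 0 as the tiebreak.

## Getis-Ord Gi*

Binary distance-band weights W_ij = 1 iff d(i,j) ≤ d, with self-inclusion
(the star convention) on by default. Gi* = Σⱼ W_ij X_j / Σⱼ X_j; the
z-score uses the standard randomization moments E[Gi*] = W_i/n and
Var[Gi*] = W_i(n−W_i)/(n²(n−1))·(S/X̄)². Categories follow |z| ≥ 1.65 /
1.96 / 2.58 (90/95/99%), signed hot/cold. Gi* assumes nonnegative values;
inputs with nonpositive entries (e.g. log-transformed services) are
shifted to be positive with the shift recorded — the z-score is invariant
to that shift, only the raw Gi* and its moments change. The default band
in the pipeline is twice the variogram lag step; isolated plots trigger a
warning, not an error. No multiple-testing correction is applied (raw
thresholds by design).

## Geographical detector

Factor q = 1 − Σ_m N_m σ_m² / (N σ²) with population variances, computed
through the exact decomposition N σ² = within + between so that the q = 0
(single stratum) and q = 1 (constant within every stratum) limits hold
exactly and q ∈ [0, 1] is guaranteed. Significance uses the
noncentral-F test: F = ((N−L)/(L−1))·q/(1−q) against F(L−1, N−L; λ) with
λ = (Σ Ȳ_h² − (Σ √N_h Ȳ_h)²/N)/σ². Empty strata are dropped with a
warning; the significance threshold defaults to p < 0.1.

Continuous drivers are discretized by Jenks natural breaks into k = 5
classes by default — the exact Fisher dynamic program (O(kn²)) minimizing
within-class sum of squares; ties break toward the lower cut, and fewer
distinct values than k reduce k with a warning.

The interaction detector computes q of the A×B cross-classification and
classifies it against min(qA,qB), max(qA,qB) and qA+qB into the standard
five classes (weakening → nonlinear enhancement); equality with qA+qB
(independence) is tested at 1e-9. Because the cross-classification refines
both inputs, q(A∩B) ≥ max(qA,qB) always holds for population-variance q.

## Synthetic survey generator

What it emulates: a plot-based survey of a ~1050 km² region (30 × 35 km)
sampled by a square raster net with a seeded random fraction of cells
excluded (standing in for inaccessible or redundant field sites) and one
plot placed uniformly inside each selected cell; lognormal service values
whose log-scale field is multivariate normal with spherical covariance
C(h) = (C−Co)(1 − 1.5h/a + 0.5(h/a)³), the nugget Co added as independent
per-plot noise (measurement-error reading of the nugget); and categorical
drivers assigned over contiguous vertical bands.

Defaults: 240 plots on a 1750 m net with 20% exclusion. A 2500 m net over
this region has only 168 cells, which cannot hold 240 one-per-cell plots;
the finer net preserves the plot count and the one-per-cell invariant at a
comparable density. The recovery experiments use a log-scale field with
Co = 0.2, C = 1.0, a = 8000 m — a strongly spatially dependent service
with unit log-variance and a range well below the region size, so the
variogram is identifiable from ~20 lag bins. The default pipeline's four
services use nuggets 0.21/0.21/0.30/0.60 to span the strong-to-weak
dependence spectrum.

Driver layers: each vertical zone receives a coefficient β_z drawn as
|Normal(0, zone_effect_sd)| (folded normal), and the continuous covariate
at a plot is β_zone·(standardized log field) + Normal(0, noise_sd). The
coefficient is a magnitude by construction: with signed coefficients the
covariate would anti-track the field in roughly half the zones, so
discretizing it would mix high and low field values within a class and cap
the achievable q near 0.2 regardless of effect size — defeating the
generator's purpose of dialling explanatory power between ~0 (pure noise)
and ~0.8 via the zone_effect_sd : noise_sd ratio. Zone geometry is
vertical bands rather than Voronoi cells for reproducibility and trivial
point-in-zone tests.

What the generator does not emulate: tree-level structure (species, DBH,
allometry), realistic land-cover geometry, anisotropy, non-stationary
means, or spatially clustered exclusions ("adjacent/similar site"
removal is approximated by random cell removal). Passing recovery tests
therefore show that the estimators are correct and calibrated under
stationary isotropic lognormal conditions — not that real surveys satisfy
those conditions.

## Experiment sizes and numerical choices

Recovery and calibration experiments use 20 replicates of 240-plot
surveys — enough for stable medians while keeping the whole suite and the
acceptance script in the tens of seconds. Cholesky simulation adds an
escalating diagonal jitter (from 1e-10·sill) only if the covariance is
numerically semi-definite. Per-replicate seeds are spawned from a single
`SeedSequence`, so every experiment is a pure function of its seed.

Known limitations: isotropic spherical-only variograms; no co-kriging or
trend surfaces; Gi* on plot values or raster cells but without FDR
control; the geodetector treats drivers as error-free strata; hold-out CV
reuses the model fitted on all data rather than refitting per split
(matching common practice in survey geostatistics, where the variogram is
treated as fixed).
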