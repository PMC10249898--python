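"""End-to-end analysis pipeline: simulate/read -> composite -> variogram ->
kriging + cross-validation -> hotspots -> geodetector, with a run manifest.

Each stage is a thin orchestration over the corresponding library module;
running the pipeline is equivalent to invoking the stages by hand with the
same seeds.  All artifacts are delimited text (CSV / ESRI ASCII / JSON) and
every output file is listed in ``manifest.json`` with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composite import composite_es, distribution_diagnostics
from .geodetector import run_geodetector
from .hotspot import distance_band_weights, getis_ord_gi_star
from .io import read_plot_table, write_plot_table, write_raster_ascii
from .kriging import cross_validate, krige_grid
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
    classify_spatial_dependence,
    empirical_semivariogram,
    fit_spherical_model,
    lag_structure,
)

__all__ = ["PipelineConfig", "default_config", "build_synthetic_table", "run_pipeline"]

logger = logging.getLogger("esgeo")


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline.

    Either ``input_path`` points at a plot-table CSV, or ``synthetic`` holds
    the generator configuration (region/design/fields/drivers).  Service
    values are log-transformed for variogram fitting and kriging
    (``transform="log"``) but composited on the raw scale.
    """

    output_dir: str = "esgeo_output"
    seed: int = 0
    input_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    services: list[str] = field(default_factory=list)
    composite_services: list[str] = field(default_factory=list)
    transform: str = "log"
    variogram: dict = field(default_factory=dict)  # overrides: lag_step, n_lags, max_dist
    kriging: dict = field(default_factory=dict)
    hotspot: dict = field(default_factory=dict)
    geodetector: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def default_config(output_dir: str = "esgeo_output", seed: int = 0) -> PipelineConfig:
    """Default synthetic study emulating a ~1050 km^2 plot survey of 240 plots.

    Four lognormal services with spherical log-scale covariance (range 8 km,
    unit sill, nuggets spanning the strong-to-weak dependence classes) and
    six zonal drivers of graded strength.
    """
    return PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        synthetic={
            "region": {"origin_x": 0.0, "origin_y": 0.0, "width_m": 30_000.0, "height_m": 35_000.0},
            "design": {"cell_size_m": 1750.0, "n_target": 240, "exclusion_fraction": 0.2},
            "fields": [
                {"service_name": "carbon_storage", "nugget": 0.21, "sill": 1.0, "range_m": 8000.0, "mean_log": 5.75},
                {"service_name": "carbon_sequestration", "nugget": 0.21, "sill": 1.0, "range_m": 8000.0, "mean_log": 4.1},
                {"service_name": "avoided_runoff", "nugget": 0.30, "sill": 1.0, "range_m": 8000.0, "mean_log": 0.2},
                {"service_name": "pollution_removal", "nugget": 0.60, "sill": 1.0, "range_m": 8000.0, "mean_log": 7.4},
            ],
            "drivers": [
                {"name": "total_population", "n_zones": 5, "zone_effect_sd": 1.5, "noise_sd": 0.4},
                {"name": "gdp_primary", "n_zones": 5, "zone_effect_sd": 1.2, "noise_sd": 0.4},
                {"name": "gdp_secondary", "n_zones": 5, "zone_effect_sd": 1.0, "noise_sd": 0.4},
                {"name": "gdp_tertiary", "n_zones": 5, "zone_effect_sd": 0.8, "noise_sd": 0.4},
                {"name": "forest_garden_grass", "n_zones": 5, "zone_effect_sd": 0.6, "noise_sd": 0.4},
                {"name": "built_up_area", "n_zones": 5, "zone_effect_sd": 0.0, "noise_sd": 0.4},
            ],
        },
        services=[
            "carbon_storage",
            "carbon_sequestration",
            "avoided_runoff",
            "pollution_removal",
        ],
        composite_services=["carbon_sequestration", "avoided_runoff", "pollution_removal"],
        kriging={"cell_size_m": 1000.0, "holdout_fraction": 0.10, "cv_mode": "holdout",
                 "back_transform": False},
        geodetector={"k": 5, "p_threshold": 0.1},
    )


def build_synthetic_table(cfg: PipelineConfig) -> tuple[pd.DataFrame, RegionSpec]:
    """Generate the synthetic plot table declared by ``cfg.synthetic``.

    Per-stage seeds are derived deterministically from the global seed so
    that fields and drivers are mutually independent but reproducible.
    """
    syn = cfg.synthetic
    if not syn:
        raise ValueError("config has no synthetic block and no input_path")
    region = RegionSpec(**syn.get("region", {}))
    design_kwargs = dict(syn.get("design", {}))
    design_kwargs.setdefault("seed", cfg.seed)
    design = SamplingDesign(**design_kwargs)
    locations = grid_random_sample(region, design)
    table = pd.DataFrame(
        {
            "plot_id": [f"P{i:04d}" for i in range(len(locations))],
            "x": locations[:, 0],
            "y": locations[:, 1],
        }
    )
    seq = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s) for s in seq.generate_state(len(syn.get("fields", [])) + len(syn.get("drivers", [])) + 1) % (2**31)]
    si = 0
    field_logs: dict[str, np.ndarray] = {}
    for f in syn.get("fields", []):
        model = VariogramModel(nugget=f["nugget"], sill=f["sill"], range_=f["range_m"])
        spec = SyntheticFieldSpec(
            model=model,
            mean_log=f.get("mean_log", 0.0),
            seed=f.get("seed", child_seeds[si]),
            service_name=f["service_name"],
        )
        si += 1
        vals = simulate_es_field(locations, spec)
        table[spec.service_name] = vals
        field_logs[spec.service_name] = np.log(vals)
    # drivers track one field's log values: an explicit "field" entry, else
    # the first composited service (the geodetector's default response side)
    default_field = None
    for candidate in [*cfg.composite_services, *field_logs]:
        if candidate in field_logs:
            default_field = candidate
            break
    for d in syn.get("drivers", []):
        kwargs = dict(d)
        kwargs.setdefault("seed", child_seeds[si])
        si += 1
        target = kwargs.pop("field", default_field)
        if target not in field_logs:
            raise ValueError(f"driver field {target!r} is not a simulated service")
        spec = DriverSpec(**kwargs)
        cols = simulate_driver_layers(
            locations, field_logs[target], spec,
            x_min=region.origin_x, x_max=region.origin_x + region.width_m,
        )
        for name, col in cols.items():
            table[name] = col
    if not cfg.services:
        cfg.services = [f["service_name"] for f in syn.get("fields", [])]
    return table, region


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns the in-memory results.

    Stage order: (synthetic generation | read) -> distribution diagnostics +
    log transform -> composite ES -> variogram fit + dependence class ->
    kriging grid + cross-validation -> hot-spot analysis -> geodetector.
    Fully deterministic given the config seeds.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- input ---------------------------------------------------------
    if cfg.input_path:
        table = read_plot_table(cfg.input_path)
        region = RegionSpec(
            origin_x=float(table["x"].min()),
            origin_y=float(table["y"].min()),
            width_m=float(table["x"].max() - table["x"].min()),
            height_m=float(table["y"].max() - table["y"].min()),
        )
    else:
        table, region = build_synthetic_table(cfg)
    services = cfg.services or []
    logger.info("pipeline input: %d plots, %d services", len(table), len(services))
    locations = table[["x", "y"]].to_numpy(dtype=float)

    # --- diagnostics ---------------------------------------------------
    diag_rows = []
    for s in services:
        for transform in ("none", "log"):
            d = distribution_diagnostics(table[s].to_numpy(), transform=transform)
            diag_rows.append(
                {"service": s, "transform": transform,
                 "skewness": d.skewness, "kurtosis": d.kurtosis, "n": d.n}
            )
    diagnostics = pd.DataFrame(diag_rows)
    diagnostics.to_csv(out / "diagnostics.csv", index=False)
    results["diagnostics"] = diagnostics

    # --- composite -----------------------------------------------------
    comp_services = cfg.composite_services or services
    comp = composite_es(table, comp_services)
    table["composite_es"] = comp.composite
    results["composite"] = comp
    write_plot_table(table, out / "plot_table.csv")

    # --- variogram + kriging + cross-validation per service ------------
    lag_cfg = cfg.variogram
    lags = lag_structure(locations, n_lags=lag_cfg.get("n_lags"))
    lag_step = lag_cfg.get("lag_step", lags.lag_step)
    n_lags = lag_cfg.get("n_lags", lags.n_lags)
    max_dist = lag_cfg.get("max_dist", lags.max_dist)
    logger.info("lag structure: step %.1f m, %d lags, max %.1f m", lag_step, n_lags, max_dist)

    krig_cfg = cfg.kriging
    variogram_rows, cv_rows = [], []
    models: dict[str, VariogramModel] = {}
    for s in services:
        vals = table[s].to_numpy(dtype=float)
        work = np.log(vals) if cfg.transform == "log" else vals
        emp = empirical_semivariogram(locations, work, lag_step, n_lags, max_dist)
        model, diag = fit_spherical_model(emp)
        cls = classify_spatial_dependence(model)
        models[s] = model
        pd.DataFrame(
            {"lag_mid_m": emp.lag_mid, "gamma": emp.gamma, "n_pairs": emp.counts}
        ).to_csv(out / f"variogram_{s}.csv", index=False)
        variogram_rows.append(
            {"service": s, "transform": cfg.transform,
             "nugget_Co": model.nugget, "sill_C": model.sill, "range_a_m": model.range_,
             "nugget_ratio_percent": cls.nugget_ratio_percent, "dependence": cls.label,
             "weighted_sse": diag.weighted_sse}
        )
        cv = cross_validate(
            table, s, model,
            mode=krig_cfg.get("cv_mode", "holdout"),
            holdout_fraction=krig_cfg.get("holdout_fraction", 0.10),
            seed=krig_cfg.get("seed", cfg.seed),
            transform=cfg.transform,
            neighborhood_size=krig_cfg.get("neighborhood_size"),
        )
        cv_rows.append(
            {"service": s, "mode": cv.mode, "ME": cv.me, "RMSE": cv.rmse,
             "n_train": cv.n_train, "n_test": cv.n_test, "seed": cv.seed}
        )
        surface = krige_grid(
            locations, work, model, region,
            cell_size_m=krig_cfg.get("cell_size_m", 1000.0),
            neighborhood_size=krig_cfg.get("neighborhood_size"),
            transform=cfg.transform,
            back_transform=krig_cfg.get("back_transform", False),
        )
        write_raster_ascii(surface, out / f"kriging_{s}.asc")
    variogram_summary = pd.DataFrame(variogram_rows)
    variogram_summary.to_csv(out / "variogram_models.csv", index=False)
    cv_summary = pd.DataFrame(cv_rows)
    cv_summary.to_csv(out / "cross_validation.csv", index=False)
    results["variogram_models"] = variogram_summary
    results["models"] = models
    results["cross_validation"] = cv_summary

    # --- hotspot -------------------------------------------------------
    hot_cfg = cfg.hotspot
    band = hot_cfg.get("distance_band", 2.0 * lag_step)
    weights = distance_band_weights(locations, band, include_self=True)
    hot_tables = {}
    for s in [*services, "composite_es"]:
        res = getis_ord_gi_star(table[s].to_numpy(dtype=float), weights)
        ht = pd.DataFrame(
            {"plot_id": table["plot_id"], "z": res.z, "category": res.category}
        )
        ht.to_csv(out / f"hotspot_{s}.csv", index=False)
        hot_tables[s] = ht
        logger.info(
            "hotspot %s: band %.0f m, %d significant at 95%%",
            s, band, int((np.abs(res.z) >= 1.96).sum()),
        )
    results["hotspots"] = hot_tables

    # --- geodetector ---------------------------------------------------
    geo_cfg = cfg.geodetector
    drivers = geo_cfg.get("drivers")
    if drivers is None:
        drivers = [
            c for c in table.columns
            if c not in ("plot_id", "x", "y", "composite_es") and c not in services
        ]
    if drivers:
        report = run_geodetector(
            table,
            y_service=geo_cfg.get("y_service", "composite_es"),
            driver_names=drivers,
            k=geo_cfg.get("k", 5),
            p_threshold=geo_cfg.get("p_threshold", 0.1),
        )
        report.factors.to_csv(out / "geodetector_factors.csv", index=False)
        report.interactions.to_csv(out / "geodetector_interactions.csv", index=False)
        results["geodetector"] = report

    # --- manifest ------------------------------------------------------
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "esgeo_version": __version__,
        "config": asdict(cfg),
        "artifacts": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    results["table"] = table
    return results
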