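"""End-to-end pipeline: simulate -> preprocess -> footprints -> train ->
predict -> correct -> validate -> compare.

:func:`run_end_to_end` executes the whole chain in memory and returns every
intermediate product; the ``stage_*`` functions are the file-based wrappers
the command-line interface runs, each reading and writing declared
artifacts under an output directory and recording checksums in a manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import agb_model, bias_correction, covariates, glas_to_agb, synthetic_data, validation_compare
from .agb_model import CBAND_FEATURES, ModelSpec, RegionStrata
from .allometry import AllometricModel, fit_power_allometry
from .config import PipelineConfig
from .covariates import CovariateStack
from .raster import Grid, read_raster, read_stack, write_raster, write_stack
from .synthetic_data import SiteData, SyntheticScene

STAGES = ["simulate", "preprocess", "footprints", "train", "predict", "correct", "validate", "compare"]


# ---------------------------------------------------------------------------
# Core computational steps (in-memory)

def build_covariate_stack(scene: SyntheticScene, cfg: PipelineConfig) -> tuple[CovariateStack, np.ndarray, np.ndarray]:
    """Assemble the co-registered covariate stack from raw scene layers.

    Returns (stack, forest_mask, cband_gap).  L-band digital numbers are
    calibrated to gamma-naught, speckle-smoothed in linear power with a
    circular focal mean, and complemented by the HV-HH ratio; the C-band
    stack reduces to pooled mean/std/min with a gap mask where fewer than
    ``min_cband_obs`` observations exist; the optical stack is
    cloud-screened and composited; terrain adds elevation and slope; and
    coordinate bands let the model absorb broad geographic gradients.
    """
    g = scene.grid
    px = g.pixel_size
    stack = CovariateStack(grid=g)

    for pol in ("hh", "hv"):
        db = covariates.dn_to_gamma0(scene.lband_dn[pol], cf=cfg.calibration_factor_db)
        lin = covariates.db_to_linear(db)
        sm = covariates.focal_mean(lin, cfg.focal_radius_m, px)
        stack.add(f"{pol}_db", covariates.linear_to_db(sm), "dB")
    stack.add("hvhh_ratio", covariates.sar_ratio(stack.bands["hv_db"], stack.bands["hh_db"]), "dB")

    cstats = covariates.envisat_stats(scene.cband_stack, min_obs=cfg.min_cband_obs)
    stack.add("c_mean", cstats["mean"], "dB")
    stack.add("c_std", cstats["std"], "dB")
    if cfg.include_c_min:
        stack.add("c_min", cstats["min"], "dB")
    cband_gap = cstats["gap"]

    comp = covariates.landsat_composite(scene.optical, scene.qa_clear)
    for name, arr in comp.items():
        stack.add(name, arr, "" if name.startswith("ndvi") else "reflectance")

    stack.add("elevation", scene.dem, "m")
    stack.add("slope", covariates.slope_from_dem(scene.dem, px), "deg")
    lat, lon = g.cell_centres()
    stack.add("lat", lat, "m")
    stack.add("lon", lon, "m")

    forest = covariates.build_forest_mask(
        scene.cover2000, scene.lossyear, target_year=cfg.target_year, threshold=cfg.cover_threshold
    ).mask
    return stack, forest, cband_gap


def fit_regional_models(cfg: PipelineConfig) -> tuple[dict[str, AllometricModel], list, list]:
    """Generate regional inventory plots and fit the two power-law allometries."""
    from .allometry import NORTH_MODEL, SOUTH_MODEL

    plots_n = synthetic_data.generate_field_plots(
        "north", cfg.n_plots_north, NORTH_MODEL, cfg.plot_scatter, seed=cfg.subseed(11)
    )
    plots_s = synthetic_data.generate_field_plots(
        "south", cfg.n_plots_south, SOUTH_MODEL, cfg.plot_scatter, seed=cfg.subseed(12)
    )
    models = {}
    for label, plots in (("north", plots_n), ("south", plots_s)):
        lorey, agb = synthetic_data.plots_to_pairs(plots)
        models[label] = fit_power_allometry(lorey, agb, region=label)
    return models, plots_n, plots_s


def feature_lists(stack: CovariateStack) -> dict[str, list[str]]:
    """Per-stratum feature lists: the gap stratum drops C-band bands."""
    full = stack.band_names
    return {
        "flat": full,
        "rugged": full,
        "no_cband": [f for f in full if f not in CBAND_FEATURES],
    }


def train_stratified(
    cells: pd.DataFrame,
    stack: CovariateStack,
    strata: RegionStrata,
    cfg: PipelineConfig,
    cell_size_px: int,
) -> dict[str, ModelSpec]:
    """Train and prune one forest per stratum.

    Flat and rugged models train on their own stratum's training cells;
    the no-C-band model trains on all training cells with the C-band
    features removed (the gap region alone rarely holds enough cells).
    """
    feats = feature_lists(stack)
    cell_stratum = assign_cell_stratum(cells, strata, cell_size_px)
    models: dict[str, ModelSpec] = {}
    for name in ("flat", "rugged", "no_cband"):
        sub = cells if name == "no_cband" else cells[cell_stratum == name]
        model = agb_model.train_region_model(
            sub, feats[name], seed=cfg.subseed(21), n_trees=cfg.n_trees, region=name
        )
        if len(model.features) > cfg.prune_k:
            model = agb_model.prune_and_retrain(model, sub, k=cfg.prune_k)
        models[name] = model
    return models


def assign_cell_stratum(cells: pd.DataFrame, strata: RegionStrata, cell_size_px: int) -> np.ndarray:
    """Majority stratum over each cell's pixels."""
    f = int(cell_size_px)
    rasters = strata.as_dict()
    out = np.empty(len(cells), dtype=object)
    for i, (cr, cc) in enumerate(zip(cells["cell_row"], cells["cell_col"])):
        counts = {k: int(v[cr * f : (cr + 1) * f, cc * f : (cc + 1) * f].sum()) for k, v in rasters.items()}
        out[i] = max(counts, key=counts.get)
    return out


def predict_stitched(
    models: dict[str, ModelSpec],
    stack: CovariateStack,
    strata: RegionStrata,
    forest_mask: np.ndarray,
) -> np.ndarray:
    maps = {name: agb_model.predict_map(models[name], stack, mask) for name, mask in strata.as_dict().items()}
    return agb_model.stitch(maps, strata, forest_mask)


def run_end_to_end(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline in memory on a synthetic scene.

    Returns a dictionary with the scene, covariate stack, allometric models,
    cell table, per-stratum forests, raw and bias-corrected maps, the
    corrector, cell-level accuracy metrics pre/post correction, site
    filtering results, site-level metrics and map summaries.
    """
    scene = synthetic_data.generate_scene(cfg.scene)
    stack, forest, cband_gap = build_covariate_stack(scene, cfg)
    allom, plots_n, plots_s = fit_regional_models(cfg)

    fp = synthetic_data.sample_footprints(scene, cfg.n_footprints, seed=cfg.subseed(1))
    fp = glas_to_agb.attach_slope(fp, stack.bands["slope"], scene.grid)
    fp = glas_to_agb.convert_heights(fp, allom, cap_m=cfg.height_cap_m)
    fp = glas_to_agb.filter_footprints(
        fp, slope_max=cfg.slope_max, slope_low=cfg.slope_low, agb_threshold=cfg.agb_filter_threshold
    )

    f = cfg.scene.cell_size_px
    cells = glas_to_agb.aggregate_to_cells(
        fp, scene.grid, f, min_count=cfg.min_footprints, stack=stack, forest_mask=forest,
        average=cfg.cell_average, models=allom,
    )
    cells = glas_to_agb.split_cells(cells, train_frac=cfg.train_frac, seed=cfg.subseed(2))

    strata = agb_model.stratify(stack.bands["slope"], cband_gap, forest, slope_split=cfg.slope_split)
    models = train_stratified(cells, stack, strata, cfg, f)
    agb_raw = predict_stitched(models, stack, strata, forest)

    r2_pre, rmse_pre, eval_cells = agb_model.evaluate_cells(
        agb_raw, cells, scene.grid, f, forest_mask=forest, subset="validation", r2_mode=cfg.r2_mode
    )
    corrector = bias_correction.fit_corrector(
        eval_cells["agb_pred"].to_numpy(), eval_cells["agb"].to_numpy(), bin_width=cfg.bin_width
    )
    agb_corrected = bias_correction.apply_corrector(corrector, agb_raw)
    r2_post, rmse_post, _ = agb_model.evaluate_cells(
        agb_corrected, cells, scene.grid, f, forest_mask=forest, subset="validation", r2_mode=cfg.r2_mode
    )

    site_data = synthetic_data.generate_validation_sites(
        scene, cfg.n_sites, cfg.fraction_unstable, cfg.fraction_heterogeneous,
        seed=cfg.subseed(3), buffer_m=cfg.buffer_m,
    )
    survivors, audit = validation_compare.filter_sites(
        site_data.sites, forest, site_data.ndvi_annual, site_data.sar_hh_annual,
        site_data.sar_hv_annual, site_data.agb_map, scene.grid,
        buffer_m=cfg.buffer_m, forest_fraction_min=cfg.forest_fraction_min,
        ndvi_fluct_max=cfg.ndvi_fluct_max, sar_fluct_max=cfg.sar_fluct_max,
        heterogeneity_max=cfg.heterogeneity_max,
    )
    site_r2, site_rmse = (float("nan"), float("nan"))
    if len(survivors) >= 2:
        site_r2, site_rmse = validation_compare.site_metrics(
            agb_corrected, survivors, scene.grid, aggregation="pixel", r2_mode=cfg.r2_mode
        )

    summary = validation_compare.summarize_map(
        agb_corrected, scene.grid.pixel_area_ha, carbon_fraction=cfg.carbon_fraction, bin_width=cfg.bin_width
    )
    boxstats = None
    if len(survivors) >= 1:
        boxstats = validation_compare.buffered_boxplot_stats(
            {"corrected": agb_corrected, "raw": agb_raw}, survivors, scene.grid,
            cell_size_m=1000.0, forest_mask=forest,
        )

    return {
        "scene": scene,
        "stack": stack,
        "forest_mask": forest,
        "cband_gap": cband_gap,
        "allometric_models": allom,
        "plots": {"north": plots_n, "south": plots_s},
        "footprints": fp,
        "cells": cells,
        "strata": strata,
        "models": models,
        "agb_raw": agb_raw,
        "agb_corrected": agb_corrected,
        "corrector": corrector,
        "metrics": {
            "r2_pre": r2_pre, "rmse_pre": rmse_pre,
            "r2_post": r2_post, "rmse_post": rmse_post,
            "site_r2": site_r2, "site_rmse": site_rmse,
        },
        "sites": site_data,
        "site_survivors": survivors,
        "site_audit": audit,
        "summary": summary,
        "boxplot_stats": boxstats,
    }


# ---------------------------------------------------------------------------
# File-based stages for the CLI

def _checksum(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    elif isinstance(obj, pd.DataFrame):
        h.update(obj.to_csv(index=False).encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


class Manifest:
    """Per-run manifest: config hash, seed and per-stage artifact checksums."""

    def __init__(self, outdir: Path, cfg: PipelineConfig):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    def record(self, stage: str, artifacts: dict) -> None:
        self.data["stages"][stage] = {k: _checksum(v) for k, v in artifacts.items()}
        self.path.write_text(json.dumps(self.data, indent=1))


def _require(outdir: Path, filename: str, needed_by: str, produced_by: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {filename}; run stage '{produced_by}' first"
        )
    return p


def save_scene(scene: SyntheticScene, outdir: Path) -> None:
    g = scene.grid
    write_raster(outdir / "scene_layers.tif", {
        "agb_true": scene.agb_true, "dem": scene.dem, "slope": scene.slope,
        "cover2000": scene.cover2000, "lossyear": scene.lossyear.astype(float),
        "region_north": scene.region_north.astype(float),
        "dn_hh": scene.lband_dn["hh"], "dn_hv": scene.lband_dn["hv"],
        "cband_count": scene.cband_count.astype(float),
    }, g, units={"agb_true": "Mg/ha", "dem": "m", "slope": "deg", "cover2000": "%"})
    write_stack(outdir / "cband_stack.tif", scene.cband_stack, g, "C-band dB observations")
    for name, st in scene.optical.items():
        write_stack(outdir / f"optical_{name}.tif", st, g, f"{name} reflectance")
    write_stack(outdir / "qa_clear.tif", scene.qa_clear.astype(float), g, "1 = clear")


def load_scene(cfg: PipelineConfig, outdir: Path) -> SyntheticScene:
    layers, g = read_raster(outdir / "scene_layers.tif")
    cband, _ = read_stack(outdir / "cband_stack.tif")
    optical = {}
    for name in ("green", "red", "nir", "swir"):
        optical[name], _ = read_stack(outdir / f"optical_{name}.tif")
    qa, _ = read_stack(outdir / "qa_clear.tif")
    forest = covariates.build_forest_mask(
        layers["cover2000"], layers["lossyear"], cfg.target_year, cfg.cover_threshold
    ).mask
    return SyntheticScene(
        config=cfg.scene, grid=g,
        agb_true=layers["agb_true"], dem=layers["dem"], slope=layers["slope"],
        cover2000=layers["cover2000"], lossyear=layers["lossyear"].astype(np.int16),
        region_north=layers["region_north"] > 0.5,
        lband_dn={"hh": layers["dn_hh"], "hv": layers["dn_hv"]},
        cband_stack=cband, cband_count=layers["cband_count"].astype(int),
        optical=optical, qa_clear=qa > 0.5, forest_mask=forest,
    )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    scene = synthetic_data.generate_scene(cfg.scene)
    save_scene(scene, outdir)
    fp = synthetic_data.sample_footprints(scene, cfg.n_footprints, seed=cfg.subseed(1))
    fp.to_csv(outdir / "footprints.csv", index=False)
    _, plots_n, plots_s = fit_regional_models(cfg)
    synthetic_data.plots_to_frame(plots_n + plots_s).to_csv(outdir / "plots.csv", index=False)
    site_data = synthetic_data.generate_validation_sites(
        scene, cfg.n_sites, cfg.fraction_unstable, cfg.fraction_heterogeneous,
        seed=cfg.subseed(3), buffer_m=cfg.buffer_m,
    )
    site_data.sites.to_csv(outdir / "sites.csv", index=False)
    write_stack(outdir / "ndvi_annual.tif", site_data.ndvi_annual, scene.grid)
    write_stack(outdir / "sar_hh_annual.tif", site_data.sar_hh_annual, scene.grid)
    write_stack(outdir / "sar_hv_annual.tif", site_data.sar_hv_annual, scene.grid)
    cfg.to_yaml(outdir / "config.yaml")
    Manifest(outdir, cfg).record("simulate", {
        "agb_true": scene.agb_true, "footprints": fp, "sites": site_data.sites,
    })


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "scene_layers.tif", "preprocess", "simulate")
    scene = load_scene(cfg, outdir)
    stack, forest, gap = build_covariate_stack(scene, cfg)
    write_raster(outdir / "stack.tif", stack.bands, stack.grid, units=stack.units)
    write_raster(outdir / "masks.tif", {
        "forest": forest.astype(float), "cband_gap": gap.astype(float),
    }, stack.grid)
    Manifest(outdir, cfg).record("preprocess", {n: stack.bands[n] for n in stack.band_names})


def _load_stack(outdir: Path) -> tuple[CovariateStack, np.ndarray, np.ndarray]:
    bands, g = read_raster(outdir / "stack.tif")
    masks, _ = read_raster(outdir / "masks.tif")
    return CovariateStack(grid=g, bands=bands), masks["forest"] > 0.5, masks["cband_gap"] > 0.5


def stage_footprints(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "stack.tif", "footprints", "preprocess")
    fp = pd.read_csv(_require(outdir, "footprints.csv", "footprints", "simulate"))
    stack, _, _ = _load_stack(outdir)
    plots = synthetic_data.frame_to_plots(pd.read_csv(outdir / "plots.csv"))
    models: dict[str, AllometricModel] = {}
    for region in ("north", "south"):
        lorey, agb = synthetic_data.plots_to_pairs([p for p in plots if p.region == region])
        models[region] = fit_power_allometry(lorey, agb, region=region)
        models[region].to_json(outdir / f"allometry_{region}.json")
    fp = glas_to_agb.attach_slope(fp, stack.bands["slope"], stack.grid)
    fp = glas_to_agb.convert_heights(fp, models, cap_m=cfg.height_cap_m)
    fp = glas_to_agb.filter_footprints(
        fp, slope_max=cfg.slope_max, slope_low=cfg.slope_low, agb_threshold=cfg.agb_filter_threshold
    )
    fp.to_csv(outdir / "footprints_qc.csv", index=False)
    Manifest(outdir, cfg).record("footprints", {"footprints_qc": fp})


def stage_train(cfg: PipelineConfig, outdir: Path) -> dict[str, ModelSpec]:
    import pickle

    fp = pd.read_csv(_require(outdir, "footprints_qc.csv", "train", "footprints"))
    stack, forest, gap = _load_stack(outdir)
    f = cfg.scene.cell_size_px
    models = {r: AllometricModel.from_json(outdir / f"allometry_{r}.json") for r in ("north", "south")}
    cells = glas_to_agb.aggregate_to_cells(
        fp, stack.grid, f, min_count=cfg.min_footprints, stack=stack, forest_mask=forest,
        average=cfg.cell_average, models=models,
    )
    cells = glas_to_agb.split_cells(cells, train_frac=cfg.train_frac, seed=cfg.subseed(2))
    cells.to_csv(outdir / "cells.csv", index=False)
    strata = agb_model.stratify(stack.bands["slope"], gap, forest, slope_split=cfg.slope_split)
    rf_models = train_stratified(cells, stack, strata, cfg, f)
    (outdir / "models.pkl").write_bytes(pickle.dumps(rf_models))
    (outdir / "models_manifest.json").write_text(
        json.dumps({k: m.manifest() for k, m in rf_models.items()}, indent=1)
    )
    Manifest(outdir, cfg).record("train", {"cells": cells})
    return rf_models


def stage_predict(cfg: PipelineConfig, outdir: Path) -> np.ndarray:
    import pickle

    _require(outdir, "models.pkl", "predict", "train")
    rf_models = pickle.loads((outdir / "models.pkl").read_bytes())
    stack, forest, gap = _load_stack(outdir)
    strata = agb_model.stratify(stack.bands["slope"], gap, forest, slope_split=cfg.slope_split)
    agb_raw = predict_stitched(rf_models, stack, strata, forest)
    write_raster(outdir / "agb_raw.tif", {"agb": agb_raw}, stack.grid, units={"agb": "Mg/ha"})
    Manifest(outdir, cfg).record("predict", {"agb_raw": agb_raw})
    return agb_raw


def stage_correct(cfg: PipelineConfig, outdir: Path) -> np.ndarray:
    bands, g = read_raster(_require(outdir, "agb_raw.tif", "correct", "predict"))
    agb_raw = bands["agb"]
    cells = pd.read_csv(_require(outdir, "cells.csv", "correct", "train"))
    _, forest, _ = _load_stack(outdir)
    f = cfg.scene.cell_size_px
    r2_pre, rmse_pre, ev = agb_model.evaluate_cells(
        agb_raw, cells, g, f, forest_mask=forest, subset="validation", r2_mode=cfg.r2_mode
    )
    corrector = bias_correction.fit_corrector(
        ev["agb_pred"].to_numpy(), ev["agb"].to_numpy(), bin_width=cfg.bin_width
    )
    corrected = bias_correction.apply_corrector(corrector, agb_raw)
    r2_post, rmse_post, _ = agb_model.evaluate_cells(
        corrected, cells, g, f, forest_mask=forest, subset="validation", r2_mode=cfg.r2_mode
    )
    write_raster(outdir / "agb_corrected.tif", {"agb": corrected}, g, units={"agb": "Mg/ha"})
    corrector.to_json(outdir / "corrector.json")
    report = {
        "slope": corrector.slope, "r2_pre": r2_pre, "rmse_pre": rmse_pre,
        "r2_post": r2_post, "rmse_post": rmse_post,
        "max_pre": float(np.nanmax(agb_raw)), "max_post": float(np.nanmax(corrected)),
    }
    (outdir / "correction_report.json").write_text(json.dumps(report, indent=1))
    Manifest(outdir, cfg).record("correct", {"agb_corrected": corrected, "report": report})
    return corrected


def stage_validate(cfg: PipelineConfig, outdir: Path) -> dict:
    bands, g = read_raster(_require(outdir, "agb_corrected.tif", "validate", "correct"))
    corrected = bands["agb"]
    sites = pd.read_csv(_require(outdir, "sites.csv", "validate", "simulate"))
    _, forest, _ = _load_stack(outdir)
    ndvi_annual, _ = read_stack(outdir / "ndvi_annual.tif")
    sar_hh, _ = read_stack(outdir / "sar_hh_annual.tif")
    sar_hv, _ = read_stack(outdir / "sar_hv_annual.tif")
    layers, _ = read_raster(outdir / "scene_layers.tif")
    survivors, audit = validation_compare.filter_sites(
        sites, forest, ndvi_annual, sar_hh, sar_hv, layers["agb_true"], g,
        buffer_m=cfg.buffer_m, forest_fraction_min=cfg.forest_fraction_min,
        ndvi_fluct_max=cfg.ndvi_fluct_max, sar_fluct_max=cfg.sar_fluct_max,
        heterogeneity_max=cfg.heterogeneity_max,
    )
    audit.to_csv(outdir / "site_audit.csv", index=False)
    metrics = {}
    if len(survivors) >= 2:
        r2, rmse = validation_compare.site_metrics(corrected, survivors, g, aggregation="pixel", r2_mode=cfg.r2_mode)
        metrics = {"site_r2": r2, "site_rmse": rmse, "n_sites": int(len(survivors))}
    (outdir / "validation_metrics.json").write_text(json.dumps(metrics, indent=1))
    Manifest(outdir, cfg).record("validate", {"audit": audit, "metrics": metrics})
    return metrics


def stage_compare(cfg: PipelineConfig, outdir: Path) -> dict:
    bands, g = read_raster(_require(outdir, "agb_corrected.tif", "compare", "correct"))
    corrected = bands["agb"]
    raw = read_raster(outdir / "agb_raw.tif")[0]["agb"]
    _, forest, _ = _load_stack(outdir)
    out = {}
    for name, m in (("corrected", corrected), ("raw", raw)):
        out[name] = validation_compare.summarize_map(
            m, g.pixel_area_ha, carbon_fraction=cfg.carbon_fraction, bin_width=cfg.bin_width
        ).to_dict()
    sites = pd.read_csv(outdir / "sites.csv") if (outdir / "sites.csv").exists() else None
    if sites is not None and len(sites):
        box = validation_compare.buffered_boxplot_stats(
            {"corrected": corrected, "raw": raw}, sites, g, cell_size_m=1000.0, forest_mask=forest
        )
        box.to_csv(outdir / "boxplot_stats.csv", index=False)
        out["boxplot_stats"] = box.to_dict(orient="list")
    (outdir / "map_summaries.json").write_text(json.dumps(out, indent=1))
    Manifest(outdir, cfg).record("compare", {"summaries": out})
    return out


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "footprints": stage_footprints,
    "train": stage_train,
    "predict": stage_predict,
    "correct": stage_correct,
    "validate": stage_validate,
    "compare": stage_compare,
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path, stages: list[str] | None = None) -> None:
    """Run the requested stages (default: all, in order) writing to outdir."""
    outdir = Path(outdir)
    stages = stages or STAGES
    order = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    for s in order:
        STAGE_FUNCS[s](cfg, outdir)
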