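"""Region-stratified random-forest extrapolation of cell AGB to a map.

The landscape is split into three mutually exclusive strata — flat terrain
(slope <= 10 degrees) with C-band coverage, rugged terrain (slope > 10
degrees) with C-band coverage, and the C-band gap region — and one
regression forest is trained per stratum on the aggregated training cells.
Each forest is pruned by variable importance: the 10 features with smallest
node purity (mean decrease in impurity) are removed and the forest refitted
on the remainder.  Per-stratum wall-to-wall predictions are stitched into a
single map and assessed cell-wise against held-out LiDAR-derived cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .covariates import CovariateStack
from .raster import Grid

#: covariate bands that depend on C-band acquisitions; excluded in the gap stratum
CBAND_FEATURES = ("c_mean", "c_std", "c_min")


@dataclass
class RegionStrata:
    """Disjoint boolean rasters partitioning the forest mask."""

    flat: np.ndarray
    rugged: np.ndarray
    no_cband: np.ndarray

    def __post_init__(self) -> None:
        if (self.flat & self.rugged).any() or (self.flat & self.no_cband).any() or (self.rugged & self.no_cband).any():
            raise ValueError("strata must be pairwise disjoint")

    @property
    def union(self) -> np.ndarray:
        return self.flat | self.rugged | self.no_cband

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"flat": self.flat, "rugged": self.rugged, "no_cband": self.no_cband}


def stratify(
    slope: np.ndarray,
    cband_gap: np.ndarray,
    forest_mask: np.ndarray,
    slope_split: float = 10.0,
) -> RegionStrata:
    """Partition forest pixels into flat / rugged / no-C-band strata.

    The C-band gap takes precedence; remaining forest splits at the slope
    threshold (flat: slope <= split).
    """
    forest = np.asarray(forest_mask, dtype=bool)
    gap = np.asarray(cband_gap, dtype=bool)
    no_cband = forest & gap
    flat = forest & ~gap & (slope <= slope_split)
    rugged = forest & ~gap & (slope > slope_split)
    return RegionStrata(flat=flat, rugged=rugged, no_cband=no_cband)


@dataclass
class ModelSpec:
    """A fitted per-stratum regression forest with its feature bookkeeping."""

    region: str
    features: list[str]
    n_trees: int
    seed: int
    estimator: RandomForestRegressor
    importances: dict[str, float]
    diagnostics: dict[str, float] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "region": self.region,
            "features": self.features,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "max_features": self.estimator.max_features,
            "importances": self.importances,
            "diagnostics": self.diagnostics,
        }


def train_region_model(
    cells: pd.DataFrame,
    features: list[str],
    seed: int = 0,
    n_trees: int = 500,
    region: str = "all",
    min_cells: int = 20,
) -> ModelSpec:
    """Fit a regression forest on training cells.

    Features must be columns of ``cells``; the target is the cell mean AGB.
    Per-split candidate count is ceil(p/3) (regression-forest convention);
    importances are mean decrease in impurity (node purity).
    """
    missing = [f for f in features if f not in cells.columns]
    if missing:
        raise KeyError(f"features missing from cell table: {missing}")
    if not features:
        raise ValueError("feature list is empty")
    train = cells[cells["split"] == "train"] if "split" in cells else cells
    train = train.dropna(subset=list(features) + ["agb"])
    if len(train) < min_cells:
        raise ValueError(f"need at least {min_cells} training cells, got {len(train)}")
    X = train[list(features)].to_numpy(dtype=float)
    y = train["agb"].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, math.ceil(len(features) / 3)),
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    imps = dict(zip(features, rf.feature_importances_.tolist()))
    return ModelSpec(
        region=region,
        features=list(features),
        n_trees=n_trees,
        seed=seed,
        estimator=rf,
        importances=imps,
        diagnostics={"n_train": float(len(train))},
    )


def prune_and_retrain(model: ModelSpec, cells: pd.DataFrame, k: int = 10) -> ModelSpec:
    """Drop the k lowest-importance features and refit.

    Ties at the cut are broken by stable input order, so pruning is
    deterministic given the seed and feature order.
    """
    p = len(model.features)
    if p <= k:
        raise ValueError(f"cannot prune {k} of {p} features")
    imp = np.array([model.importances[f] for f in model.features])
    drop = set(np.argsort(imp, kind="stable")[:k].tolist())
    keep = [f for i, f in enumerate(model.features) if i not in drop]
    pruned = train_region_model(
        cells, keep, seed=model.seed, n_trees=model.n_trees, region=model.region
    )
    pruned.diagnostics["pruned_from"] = float(p)
    return pruned


def predict_map(model: ModelSpec, stack: CovariateStack, region_mask: np.ndarray) -> np.ndarray:
    """Per-pixel forest predictions inside the mask; NaN outside.

    Pixels with any missing feature band value stay NaN.  Predictions are
    clipped at zero (AGB is nonnegative).
    """
    mask = np.asarray(region_mask, dtype=bool)
    out = np.full(stack.grid.shape, np.nan)
    valid = mask & stack.valid_mask(model.features)
    if not valid.any():
        return out
    X = stack.feature_table(model.features, valid)
    out[valid] = np.maximum(model.estimator.predict(X), 0.0)
    return out


def stitch(maps: dict[str, np.ndarray], strata: RegionStrata, forest_mask: np.ndarray) -> np.ndarray:
    """Compose per-stratum maps into one raster (each pixel from its stratum).

    Raises if any forest pixel is claimed by no stratum.  Pixels whose
    stratum map is nodata (e.g. covariates missing everywhere) stay nodata.
    """
    unclaimed = forest_mask & ~strata.union
    if unclaimed.any():
        raise ValueError(f"{int(unclaimed.sum())} forest pixels belong to no stratum")
    out = np.full(forest_mask.shape, np.nan)
    for name, m in strata.as_dict().items():
        if name not in maps:
            raise KeyError(f"no map supplied for stratum {name!r}")
        out[m] = maps[name][m]
    return out


def cell_mean_prediction(
    pred: np.ndarray,
    cells: pd.DataFrame,
    grid: Grid,
    cell_size_px: int,
    forest_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean predicted AGB over each cell's (forest) pixels, NaN-aware."""
    f = int(cell_size_px)
    out = np.full(len(cells), np.nan)
    for i, (cr, cc) in enumerate(zip(cells["cell_row"], cells["cell_col"])):
        r0, c0 = int(cr) * f, int(cc) * f
        block = pred[r0 : r0 + f, c0 : c0 + f]
        sel = np.isfinite(block)
        if forest_mask is not None:
            sel &= forest_mask[r0 : r0 + f, c0 : c0 + f]
        if sel.any():
            out[i] = block[sel].mean()
    return out


def r2_rmse(pred: np.ndarray, ref: np.ndarray, r2_mode: str = "pearson") -> tuple[float, float]:
    """Agreement metrics on paired finite values.

    ``r2_mode='pearson'`` (default) returns the squared Pearson correlation;
    ``'sse'`` returns 1 - SSE/SST.  Zero variance in the reference makes
    R^2 undefined (NaN).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(ref)
    pred, ref = pred[ok], ref[ok]
    if pred.size < 2:
        raise ValueError("need at least 2 paired values")
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    if np.ptp(ref) == 0:
        return float("nan"), rmse
    if r2_mode == "pearson":
        if np.ptp(pred) == 0:
            return float("nan"), rmse
        r2 = float(np.corrcoef(pred, ref)[0, 1] ** 2)
    elif r2_mode == "sse":
        r2 = float(1.0 - np.sum((ref - pred) ** 2) / np.sum((ref - ref.mean()) ** 2))
    else:
        raise ValueError("r2_mode must be 'pearson' or 'sse'")
    return r2, rmse


def evaluate_cells(
    pred: np.ndarray,
    cells: pd.DataFrame,
    grid: Grid,
    cell_size_px: int,
    forest_mask: np.ndarray | None = None,
    subset: str | None = "validation",
    r2_mode: str = "pearson",
) -> tuple[float, float, pd.DataFrame]:
    """Cell-level R^2 and RMSE of a predicted map against LiDAR-derived cells.

    Pixel predictions are averaged within each cell before comparison.
    Returns (R^2, RMSE, per-cell table with ``agb`` and ``agb_pred``).
    """
    use = cells if subset is None or "split" not in cells else cells[cells["split"] == subset]
    if len(use) < 2:
        raise ValueError("need at least 2 cells to evaluate")
    use = use.copy()
    use["agb_pred"] = cell_mean_prediction(pred, use, grid, cell_size_px, forest_mask)
    r2, rmse = r2_rmse(use["agb_pred"].to_numpy(), use["agb"].to_numpy(), r2_mode=r2_mode)
    return r2, rmse, use
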