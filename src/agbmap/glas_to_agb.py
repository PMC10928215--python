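"""LiDAR footprint QC, height-to-AGB conversion and aggregation to cells.

Footprint tables are plain pandas DataFrames with columns
``id, x, y, lorey, slope, region`` (plus ``row, col`` when synthetic) and
gain ``agb``, ``flags`` and ``kept`` columns as they move through the
pipeline.  QC flags: ``SLOPE_GT15`` (terrain too steep for reliable height
retrieval), ``SLOPE12_15_LOWAGB`` (moderate slope combined with low biomass,
where relief rivals tree height), ``CAPPED`` (height clamped to the cap),
``MISSING_SLOPE`` (no terrain information, dropped).

The default conversion caps observed Lorey's height at 25 m, predicts AGB
per footprint with the footprint's regional allometry, and averages AGB
within square aggregation cells, keeping cells with at least two footprints.
Averaging heights first and converting the cell-mean height instead is
available via ``average="height"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allometry import AllometricModel, predict_agb_from_lorey
from .covariates import CovariateStack
from .raster import Grid

FLAG_SLOPE = "SLOPE_GT15"
FLAG_SLOPE_LOWAGB = "SLOPE12_15_LOWAGB"
FLAG_CAPPED = "CAPPED"
FLAG_MISSING_SLOPE = "MISSING_SLOPE"


def _append_flag(flags: pd.Series, sel: np.ndarray, flag: str) -> pd.Series:
    flags = flags.copy()
    flags[sel] = np.where(flags[sel] == "", flag, flags[sel] + ";" + flag)
    return flags


def attach_slope(fp: pd.DataFrame, slope: np.ndarray, grid: Grid) -> pd.DataFrame:
    """Attach the slope-band value at each footprint's centre pixel."""
    fp = fp.copy()
    row, col = grid.xy_to_rowcol(fp["x"].to_numpy(), fp["y"].to_numpy())
    inside = grid.contains(row, col)
    vals = np.full(len(fp), np.nan)
    vals[inside] = slope[row[inside], col[inside]]
    fp["slope"] = vals
    return fp


def convert_heights(
    fp: pd.DataFrame,
    models: dict[str, AllometricModel],
    cap_m: float = 25.0,
) -> pd.DataFrame:
    """Cap Lorey's heights and convert them to AGB with regional allometries.

    Heights above ``cap_m`` are clamped (flag ``CAPPED``); AGB is predicted
    from the capped height by the model of the footprint's region.  Unknown
    regions raise, listing the offending footprint ids.
    """
    fp = fp.copy()
    if "flags" not in fp:
        fp["flags"] = ""
    regions = fp["region"].to_numpy()
    unknown = ~np.isin(regions, list(models))
    if unknown.any():
        raise KeyError(f"no allometric model for region(s) of footprints {fp.loc[unknown, 'id'].tolist()}")
    h = fp["lorey"].to_numpy(dtype=float)
    capped = h > cap_m
    fp["flags"] = _append_flag(fp["flags"], capped, FLAG_CAPPED)
    h = np.minimum(h, cap_m)
    fp["lorey_capped"] = h
    agb = np.empty(len(fp))
    for lab, model in models.items():
        sel = regions == lab
        if sel.any():
            agb[sel] = predict_agb_from_lorey(model, h[sel])
    fp["agb"] = agb
    return fp


def filter_footprints(
    fp: pd.DataFrame,
    slope_max: float = 15.0,
    slope_low: float = 12.0,
    agb_threshold: float = 40.0,
) -> pd.DataFrame:
    """Apply the terrain QC rules; requires ``agb`` (convert first).

    Drops footprints on slopes > 15 degrees, and footprints on slopes in
    (12, 15] degrees whose AGB <= 40 Mg ha^-1; footprints with missing slope
    are dropped too.  Rows are retained with their flags and a boolean
    ``kept`` column; the operation is idempotent and order-independent.
    """
    if "agb" not in fp:
        raise ValueError("footprints must carry AGB before filtering (run convert_heights)")
    fp = fp.copy()
    if "flags" not in fp:
        fp["flags"] = ""
    slope = fp["slope"].to_numpy(dtype=float)
    agb = fp["agb"].to_numpy(dtype=float)
    missing = ~np.isfinite(slope)
    steep = np.isfinite(slope) & (slope > slope_max)
    moderate = np.isfinite(slope) & (slope > slope_low) & (slope <= slope_max) & (agb <= agb_threshold)
    for sel, flag in ((missing, FLAG_MISSING_SLOPE), (steep, FLAG_SLOPE), (moderate, FLAG_SLOPE_LOWAGB)):
        already = fp["flags"].str.contains(flag, regex=False).to_numpy()
        fp["flags"] = _append_flag(fp["flags"], sel & ~already, flag)
    fp["kept"] = ~(missing | steep | moderate)
    return fp


def kept(fp: pd.DataFrame) -> pd.DataFrame:
    """The footprints surviving QC (identity if no filter has run)."""
    return fp[fp["kept"]] if "kept" in fp else fp


def aggregate_to_cells(
    fp: pd.DataFrame,
    grid: Grid,
    cell_size_px: int,
    min_count: int = 2,
    stack: CovariateStack | None = None,
    forest_mask: np.ndarray | None = None,
    average: str = "agb",
    models: dict[str, AllometricModel] | None = None,
) -> pd.DataFrame:
    """Average footprint AGB within square cells and attach cell covariates.

    Cells are ``cell_size_px`` pixels on a side, anchored at the grid
    origin; only cells with at least ``min_count`` surviving footprints are
    retained.  With ``average="agb"`` (default) per-footprint AGB is
    averaged; with ``average="height"`` the cell-mean capped height is
    converted through the cell's majority-region model (requires ``models``).
    When a covariate ``stack`` is given, each retained cell gets the mean of
    every band over the cell's (forest) pixels.
    """
    fp = kept(fp)
    cols = ["cell_row", "cell_col", "x", "y", "agb", "n_footprints"]
    if fp.empty:
        return pd.DataFrame(columns=cols)
    if average not in ("agb", "height"):
        raise ValueError("average must be 'agb' or 'height'")
    f = int(cell_size_px)
    row, col = grid.xy_to_rowcol(fp["x"].to_numpy(), fp["y"].to_numpy())
    fp = fp.assign(cell_row=row // f, cell_col=col // f)
    grouped = fp.groupby(["cell_row", "cell_col"])
    agg = grouped.agg(n_footprints=("id", "size"), agb=("agb", "mean"))
    if average == "height":
        if models is None:
            raise ValueError("average='height' needs the regional models")
        mh = grouped["lorey_capped"].mean()
        maj = grouped["region"].agg(lambda s: s.mode().iloc[0])
        agg["agb"] = [predict_agb_from_lorey(models[m], h) for m, h in zip(maj, mh)]
    agg = agg[agg["n_footprints"] >= min_count].reset_index()
    cell_m = f * grid.pixel_size
    agg["x"] = grid.x0 + (agg["cell_col"] + 0.5) * cell_m
    agg["y"] = grid.y0 + (agg["cell_row"] + 0.5) * cell_m
    if stack is not None:
        means = _cell_band_means(agg, stack, f, forest_mask)
        agg = pd.concat([agg, means], axis=1)
    return agg[cols + [c for c in agg.columns if c not in cols]]


def _cell_band_means(cells: pd.DataFrame, stack: CovariateStack, f: int, forest_mask: np.ndarray | None) -> pd.DataFrame:
    g = stack.grid
    out = {name: np.full(len(cells), np.nan) for name in stack.band_names}
    for i, (cr, cc) in enumerate(zip(cells["cell_row"], cells["cell_col"])):
        r0, c0 = int(cr) * f, int(cc) * f
        sl = (slice(r0, min(r0 + f, g.rows)), slice(c0, min(c0 + f, g.cols)))
        sel = forest_mask[sl] if forest_mask is not None else np.ones((sl[0].stop - r0, sl[1].stop - c0), bool)
        for name in stack.band_names:
            block = stack.bands[name][sl][sel]
            block = block[np.isfinite(block)]
            if block.size:
                out[name][i] = block.mean()
    return pd.DataFrame(out, index=cells.index)


def split_cells(cells: pd.DataFrame, train_frac: float = 0.6, seed: int = 0) -> pd.DataFrame:
    """Random train/validation split of cells; proportions within one cell
    of the target fraction, reproducible for a fixed seed."""
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    n = len(cells)
    n_train = int(round(train_frac * n))
    perm = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:]] = "validation"
    out = cells.copy()
    out["split"] = split
    return out
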