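"""Sensor preprocessing: radar calibration, speckle smoothing, temporal
composites, terrain slope and forest masking, producing the co-registered
covariate stack the extrapolation model trains on.

Conventions
-----------
* Radar backscatter bands are gamma-naught in dB; digital numbers are
  calibrated with ``gamma0 = 10 log10(DN^2) + CF`` (mosaic calibration
  factor CF = -83.0 dB by default).
* Spatial smoothing of backscatter is done in the linear power domain —
  averaging dB values would bias the mean — with a circular focal kernel.
* Invalid pixels are NaN; every derived band carries NaN where undefined.
* "Fluctuation" of an annual series means max - min over the series.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import Grid

#: default mosaic calibration factor, dB
CALIBRATION_FACTOR_DB = -83.0


# ---------------------------------------------------------------------------
# dB / linear helpers and L-band calibration

def db_to_linear(db: np.ndarray) -> np.ndarray:
    return np.power(10.0, np.asarray(db, dtype=float) / 10.0)


def linear_to_db(lin: np.ndarray) -> np.ndarray:
    lin = np.asarray(lin, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 10.0 * np.log10(lin)
    return np.where(lin > 0, out, np.nan)


def dn_to_gamma0(dn: float | np.ndarray, cf: float = CALIBRATION_FACTOR_DB) -> float | np.ndarray:
    """Calibrate mosaic digital numbers to gamma-naught backscatter (dB).

    Non-positive DN is nodata and yields NaN rather than raising, so masks
    propagate through the calibration.
    """
    dn_arr = np.asarray(dn, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 10.0 * np.log10(dn_arr**2) + cf
    out = np.where(dn_arr > 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


def circular_kernel(radius_m: float, pixel_size: float) -> np.ndarray:
    """Boolean disc kernel of the given metric radius."""
    r_px = radius_m / pixel_size
    n = int(np.floor(r_px))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (yy**2 + xx**2) <= r_px**2 + 1e-9


def focal_mean(raster: np.ndarray, radius_m: float, pixel_size: float) -> np.ndarray:
    """Circular-kernel focal mean, NaN-aware (nodata excluded from the mean).

    Intended for speckle reduction; call on linear-power backscatter before
    dB conversion.
    """
    if radius_m < pixel_size:
        raise ValueError("focal radius must be at least one pixel")
    k = circular_kernel(radius_m, pixel_size).astype(float)
    x = np.asarray(raster, dtype=float)
    valid = np.isfinite(x)
    num = ndimage.convolve(np.where(valid, x, 0.0), k, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def sar_ratio(hv_db: np.ndarray, hh_db: np.ndarray) -> np.ndarray:
    """Cross/co-polarised ratio band: HV - HH in dB (linear-power ratio)."""
    return np.asarray(hv_db, dtype=float) - np.asarray(hh_db, dtype=float)


# ---------------------------------------------------------------------------
# C-band temporal statistics

def envisat_stats(
    stacks: list[np.ndarray] | np.ndarray,
    min_obs: int = 2,
) -> dict[str, np.ndarray]:
    """Pooled per-pixel temporal statistics of C-band backscatter (dB).

    ``stacks`` is one or more (n_obs, rows, cols) arrays (e.g. the HH and the
    VV acquisitions); the polarisations are pooled into a single per-pixel
    sample.  Missing observations are NaN.  Pixels with fewer than
    ``min_obs`` pooled observations are flagged as gap and get NaN
    statistics — these form the stratum mapped without C-band features.

    Returns ``{"mean", "std", "min", "count", "gap"}``; std is the sample
    (n-1) standard deviation, NaN where count < 2.
    """
    if isinstance(stacks, np.ndarray):
        stacks = [stacks]
    if not stacks:
        raise ValueError("at least one stack required")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in stacks], axis=0)
    count = np.sum(np.isfinite(pooled), axis=0)
    gap = count < min_obs
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(pooled), pooled, np.nan), axis=0)
        std = np.nanstd(pooled, axis=0, ddof=1)
        mn = np.nanmin(pooled, axis=0)
    for arr in (mean, std, mn):
        arr[gap] = np.nan
    return {"mean": mean, "std": std, "min": mn, "count": count, "gap": gap}


# ---------------------------------------------------------------------------
# Optical temporal compositing

def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir - red) / (nir + red)
    return np.where(nir + red != 0, out, np.nan)


def landsat_composite(
    bands: dict[str, np.ndarray],
    qa_clear: np.ndarray,
    red_band: str = "red",
    nir_band: str = "nir",
) -> dict[str, np.ndarray]:
    """Cloud-screened temporal composite of an optical reflectance stack.

    ``bands`` maps band name -> (n_obs, rows, cols) reflectance stack;
    ``qa_clear`` is the per-observation boolean clear-sky flag (False =
    cloud/shadow, excluded).  Returns per-band temporal means
    (``mean_<band>``) plus NDVI max, min and max-min difference.  Pixels
    with zero clear observations are NaN throughout.
    """
    qa = np.asarray(qa_clear, dtype=bool)
    out: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for name, stack in bands.items():
            masked = np.where(qa, np.asarray(stack, dtype=float), np.nan)
            out[f"mean_{name}"] = np.nanmean(masked, axis=0)
        nd = ndvi(np.asarray(bands[nir_band], dtype=float), np.asarray(bands[red_band], dtype=float))
        nd = np.where(qa, nd, np.nan)
        out["ndvi_max"] = np.nanmax(nd, axis=0)
        out["ndvi_min"] = np.nanmin(nd, axis=0)
    out["ndvi_diff"] = out["ndvi_max"] - out["ndvi_min"]
    return out


# ---------------------------------------------------------------------------
# Terrain

def slope_from_dem(dem: np.ndarray, pixel_size: float) -> np.ndarray:
    """Terrain slope in degrees by Horn's 3x3 finite differences.

    Border pixels use replicated edges.
    """
    z = np.pad(np.asarray(dem, dtype=float), 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * pixel_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * pixel_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


# ---------------------------------------------------------------------------
# Forest mask

@dataclass
class ForestMask:
    mask: np.ndarray
    year: int


def build_forest_mask(
    cover2000: np.ndarray,
    lossyear: np.ndarray,
    target_year: int = 2007,
    threshold: float = 10.0,
) -> ForestMask:
    """Baseline-cover/loss-year forest mask for the target year.

    Forest iff canopy cover in 2000 is strictly greater than ``threshold``
    percent and the pixel was not flagged as lost in 2001..target_year
    (``lossyear`` holds the calendar year of loss, 0 = no loss).
    """
    cover = np.asarray(cover2000, dtype=float)
    loss = np.asarray(lossyear)
    lost = (loss > 2000) & (loss <= target_year)
    return ForestMask(mask=(cover > threshold) & ~lost, year=target_year)


# ---------------------------------------------------------------------------
# Resampling

def resample_to_grid(raster: np.ndarray, source: Grid, target: Grid, categorical: bool = False) -> np.ndarray:
    """Resample a raster between aligned grids.

    Continuous bands are aggregated by (NaN-aware) area-weighted block
    averaging when the target pixel is an integer multiple of the source
    pixel, and replicated on integer refinement; categorical/mask bands use
    nearest neighbour.  The two grids must share an origin and overlap.
    """
    if (source.x0, source.y0) != (target.x0, target.y0):
        raise ValueError("grids must share an origin")
    x = np.asarray(raster, dtype=float)
    if x.shape != source.shape:
        raise ValueError("raster shape does not match source grid")
    ratio = target.pixel_size / source.pixel_size
    if abs(ratio - round(ratio)) < 1e-9 and ratio >= 1:  # aggregate
        f = int(round(ratio))
        if source.rows < f or source.cols < f:
            raise ValueError("grids do not overlap at the target resolution")
        r, c = target.rows * f, target.cols * f
        if r > source.rows or c > source.cols:
            raise ValueError("target grid extends beyond the source raster")
        blocks = x[:r, :c].reshape(target.rows, f, target.cols, f)
        if categorical:
            return blocks[:, 0, :, 0].copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(blocks, axis=(1, 3))
    inv = source.pixel_size / target.pixel_size
    if abs(inv - round(inv)) < 1e-9 and inv >= 1:  # refine
        f = int(round(inv))
        out = np.repeat(np.repeat(x, f, axis=0), f, axis=1)
        return out[: target.rows, : target.cols]
    raise ValueError("only integer resampling ratios between aligned grids are supported")


# ---------------------------------------------------------------------------
# The assembled covariate stack

@dataclass
class CovariateStack:
    """Named co-registered covariate bands on a common grid.

    ``bands`` maps band name -> 2-D float array (NaN = invalid).  Band
    validity is simply finiteness; :meth:`valid_mask` gives the conjunction
    over a band subset.
    """

    grid: Grid
    bands: dict[str, np.ndarray] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"band {name!r} shape mismatch with grid")

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    def add(self, name: str, array: np.ndarray, unit: str = "") -> None:
        if array.shape != self.grid.shape:
            raise ValueError(f"band {name!r} shape mismatch with grid")
        self.bands[name] = np.asarray(array, dtype=float)
        if unit:
            self.units[name] = unit

    def valid_mask(self, names: list[str] | None = None) -> np.ndarray:
        names = names or self.band_names
        m = np.ones(self.grid.shape, dtype=bool)
        for n in names:
            m &= np.isfinite(self.bands[n])
        return m

    def feature_table(self, names: list[str], mask: np.ndarray) -> np.ndarray:
        """(n_pixels, n_features) matrix of the masked pixels, row-major order."""
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"bands missing from stack: {missing}")
        return np.column_stack([self.bands[n][mask] for n in names])
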