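"""Synthetic scenes, LiDAR footprints, field plots and validation sites.

The generator emulates the statistical structure the mapping pipeline
assumes, so every downstream stage is testable without satellite archives:

* a latent aboveground-biomass (AGB) surface — a Gaussian random field with
  configurable correlation length, rescaled to a target range;
* saturating sensor responses of the family ``y = c0 + c1 (1 - exp(-AGB/k))``
  for L-band backscatter (HH/HV digital-number mosaics with multiplicative
  speckle), C-band backscatter time stacks with per-pixel observation
  counts (including a contiguous gap region with < 2 observations), and
  optical reflectance stacks with cloud-contaminated observations flagged
  in a QA layer;
* a smooth DEM producing both flat (<= 10 degrees) and rugged terrain;
* LiDAR footprints whose observed Lorey's height is the inverse regional
  allometry of true AGB plus Gaussian noise (default RMSE 5.9 m);
* tree-level inventory plots consistent, up to configurable scatter, with a
  target power-law height-biomass allometry;
* validation sites with constructed, book-kept pass/fail status for each
  site-filtering criterion.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import covariates
from .allometry import (
    AllometricModel,
    REFERENCE_MODELS,
    invert_lorey_from_agb,
    loreys_height,
    plot_agb_density,
    TreePlot,
    TreeRecord,
    TREE_AGB_COEF,
    TREE_AGB_EXP,
)
from .covariates import CALIBRATION_FACTOR_DB, build_forest_mask
from .raster import Grid


@dataclass(frozen=True)
class SaturatingResponse:
    """Saturating sensor response y = c0 + c1 * (1 - exp(-AGB / k))."""

    c0: float
    c1: float
    k: float

    def __call__(self, agb: np.ndarray) -> np.ndarray:
        return self.c0 + self.c1 * (1.0 - np.exp(-np.asarray(agb, dtype=float) / self.k))


#: default sensor response curves (dB for radar, reflectance/index for optical)
DEFAULT_RESPONSES: dict[str, SaturatingResponse] = {
    "lband_hv": SaturatingResponse(-18.0, 9.0, 70.0),
    "lband_hh": SaturatingResponse(-12.0, 6.0, 45.0),
    "cband": SaturatingResponse(-13.0, 4.0, 80.0),
    "ndvi": SaturatingResponse(0.15, 0.70, 60.0),
    "nir": SaturatingResponse(0.30, 0.05, 60.0),
    "green": SaturatingResponse(0.08, 0.04, 60.0),
    "swir": SaturatingResponse(0.25, -0.10, 80.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of a synthetic scene.

    ``sensor_noise_rel`` scales every sensor's noise standard deviation as a
    fraction of that sensor's dynamic range (``c1``); ``height_noise_sd`` is
    the Gaussian error of observed Lorey's height in metres.
    """

    rows: int = 200
    cols: int = 200
    pixel_size: float = 50.0
    x0: float = 0.0
    y0: float = 0.0
    agb_range: tuple[float, float] = (0.0, 250.0)
    correlation_length_px: float = 10.0
    sensor_noise_rel: float = 0.10
    height_noise_sd: float = 5.9
    cloud_fraction: float = 0.10
    n_optical_obs: int = 6
    cband_mean_obs: float = 5.0
    cband_gap_fraction: float = 0.05
    cell_size_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.agb_range[0] < 0 or self.agb_range[1] <= self.agb_range[0]:
            raise ValueError("AGB range must be nonnegative and increasing")
        if self.sensor_noise_rel < 0 or self.height_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if not 0 <= self.cloud_fraction <= 1:
            raise ValueError("cloud fraction must be in [0, 1]")

    @property
    def grid(self) -> Grid:
        return Grid(self.rows, self.cols, self.pixel_size, self.x0, self.y0)


@dataclass
class SyntheticScene:
    """All layers of one synthetic scene, co-registered on ``grid``."""

    config: SceneConfig
    grid: Grid
    agb_true: np.ndarray
    dem: np.ndarray
    slope: np.ndarray
    cover2000: np.ndarray
    lossyear: np.ndarray
    region_north: np.ndarray  # bool: True = northern allometric region
    lband_dn: dict[str, np.ndarray]  # 'hh', 'hv' digital-number mosaics
    cband_stack: np.ndarray  # (n_obs, rows, cols), NaN = missing
    cband_count: np.ndarray  # per-pixel observation count
    optical: dict[str, np.ndarray]  # band -> (n_obs, rows, cols)
    qa_clear: np.ndarray  # (n_obs, rows, cols) bool, False = cloud/shadow
    forest_mask: np.ndarray  # bool, baseline cover > 10% and not lost by 2007

    def region_label(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return np.where(self.region_north[row, col], "north", "south")


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardised to zero mean / unit sd."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a complete synthetic scene from a configuration."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    shape = grid.shape
    px = config.pixel_size

    # latent AGB: smoothed Gaussian field, rank-flattened to a uniform
    # marginal over the configured range (a monotone transform of the
    # random field, so spatial structure is preserved while the scene
    # spans the whole AGB range instead of clustering mid-range)
    f = _smooth_unit_field(rng, shape, config.correlation_length_px)
    lo, hi = config.agb_range
    ranks = np.empty(f.size)
    ranks[np.argsort(f, axis=None, kind="stable")] = np.arange(f.size)
    agb = lo + (hi - lo) * ((ranks + 0.5) / f.size).reshape(shape)

    # terrain: long-wavelength surface; amplitude gives slopes spanning
    # flat (<=10 deg) and rugged (>10 deg) areas at 50 m pixels
    dem = 100.0 * _smooth_unit_field(rng, shape, 12.0) + 800.0
    slope = covariates.slope_from_dem(dem, px)

    # forest cover and loss year
    cover = np.clip(55.0 + 35.0 * _smooth_unit_field(rng, shape, 8.0), 0.0, 100.0)
    lossyear = np.zeros(shape, dtype=np.int16)
    lost = rng.random(shape) < 0.03
    lossyear[lost] = rng.integers(2001, 2013, size=int(lost.sum()))
    forest = build_forest_mask(cover, lossyear, target_year=2007, threshold=10.0).mask

    # allometric regions: northern half of the frame is 'north'
    region_north = np.zeros(shape, dtype=bool)
    region_north[: grid.rows // 2, :] = True

    rel = config.sensor_noise_rel

    # L-band mosaics: saturating dB response, multiplicative speckle in
    # linear power, then inverse calibration back to digital numbers
    lband_dn: dict[str, np.ndarray] = {}
    for pol, resp_name in (("hh", "lband_hh"), ("hv", "lband_hv")):
        resp = DEFAULT_RESPONSES[resp_name]
        lin = covariates.db_to_linear(resp(agb))
        if rel > 0:
            shape_par = 1.0 / rel**2
            lin = lin * rng.gamma(shape_par, 1.0 / shape_par, size=shape)
        db = covariates.linear_to_db(lin)
        lband_dn[pol] = np.power(10.0, (db - CALIBRATION_FACTOR_DB) / 20.0)

    # C-band stack with per-pixel observation counts and a contiguous gap
    count = rng.poisson(config.cband_mean_obs, size=shape)
    if config.cband_gap_fraction > 0:
        gap_r = np.sqrt(config.cband_gap_fraction * grid.rows * grid.cols / np.pi)
        cy = rng.uniform(gap_r, grid.rows - gap_r)
        cx = rng.uniform(gap_r, grid.cols - gap_r)
        yy, xx = np.mgrid[0 : grid.rows, 0 : grid.cols]
        in_gap = (yy - cy) ** 2 + (xx - cx) ** 2 <= gap_r**2
        count[in_gap] = rng.integers(0, 2, size=int(in_gap.sum()))
    n_obs_c = max(int(count.max()), 1)
    c_resp = DEFAULT_RESPONSES["cband"]
    c_true = c_resp(agb)
    noise_sd_c = rel * abs(c_resp.c1)
    cband = np.full((n_obs_c, *shape), np.nan)
    for t in range(n_obs_c):
        have = count > t
        obs = c_true + (rng.normal(0.0, noise_sd_c, size=shape) if noise_sd_c > 0 else 0.0)
        cband[t][have] = obs[have]

    # optical stack: NDVI-consistent reflectances plus clouds flagged in QA
    n_opt = config.n_optical_obs
    ndvi_true = DEFAULT_RESPONSES["ndvi"](agb)
    nir_true = DEFAULT_RESPONSES["nir"](agb)
    red_true = nir_true * (1.0 - ndvi_true) / (1.0 + ndvi_true)
    base = {
        "green": DEFAULT_RESPONSES["green"](agb),
        "red": red_true,
        "nir": nir_true,
        "swir": DEFAULT_RESPONSES["swir"](agb),
    }
    noise_sd = {
        "green": rel * abs(DEFAULT_RESPONSES["green"].c1),
        "red": rel * abs(DEFAULT_RESPONSES["nir"].c1),
        "nir": rel * abs(DEFAULT_RESPONSES["nir"].c1),
        "swir": rel * abs(DEFAULT_RESPONSES["swir"].c1),
    }
    cloudy = rng.random((n_opt, *shape)) < config.cloud_fraction
    optical: dict[str, np.ndarray] = {}
    for name, truth in base.items():
        stack = np.empty((n_opt, *shape))
        for t in range(n_opt):
            sd = noise_sd[name]
            stack[t] = truth + (rng.normal(0.0, sd, size=shape) if sd > 0 else 0.0)
        cloud_val = 0.40 if name == "swir" else 0.55
        stack[cloudy] = cloud_val
        optical[name] = np.clip(stack, 0.0, 1.0)

    return SyntheticScene(
        config=config,
        grid=grid,
        agb_true=agb,
        dem=dem,
        slope=slope,
        cover2000=cover,
        lossyear=lossyear,
        region_north=region_north,
        lband_dn=lband_dn,
        cband_stack=cband,
        cband_count=count,
        optical=optical,
        qa_clear=~cloudy,
        forest_mask=forest,
    )


# ---------------------------------------------------------------------------
# LiDAR footprints

def sample_footprints(
    scene: SyntheticScene,
    n: int,
    seed: int,
    height_noise_sd: float | None = None,
    models: dict[str, AllometricModel] | None = None,
) -> pd.DataFrame:
    """Sample LiDAR footprints on forest pixels.

    True Lorey's height is obtained by inverting the region's generating
    allometry from true AGB; the observed height adds Gaussian noise
    (default: the scene's configured sd) floored at zero.  Returns a
    footprint table with columns ``id, x, y, row, col, lorey, lorey_true,
    slope, region``.
    """
    if n <= 0:
        raise ValueError("footprint count must be positive")
    models = models or REFERENCE_MODELS
    sd = scene.config.height_noise_sd if height_noise_sd is None else height_noise_sd
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(scene.forest_mask)
    if rows.size == 0:
        raise ValueError("scene has no forest pixels to sample footprints from")
    idx = rng.choice(rows.size, size=n, replace=n > rows.size)
    r, c = rows[idx], cols[idx]
    region = scene.region_label(r, c)
    agb = scene.agb_true[r, c]
    lorey_true = np.empty(n)
    for lab, model in models.items():
        sel = region == lab
        lorey_true[sel] = invert_lorey_from_agb(model, agb[sel])
    lorey = lorey_true + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    lorey = np.maximum(lorey, 0.0)
    g = scene.grid
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x": g.x0 + (c + 0.5) * g.pixel_size,
            "y": g.y0 + (r + 0.5) * g.pixel_size,
            "row": r,
            "col": c,
            "lorey": lorey,
            "lorey_true": lorey_true,
            "slope": scene.slope[r, c],
            "region": region,
        }
    )


# ---------------------------------------------------------------------------
# Field plots

def generate_field_plots(
    region: str,
    n_plots: int,
    model: AllometricModel,
    scatter: float,
    seed: int,
    area_ha: float = 0.05,
    lorey_range: tuple[float, float] = (6.0, 24.0),
) -> list[TreePlot]:
    """Generate tree-level inventory plots consistent with a target allometry.

    Each plot receives a stand Lorey's height L drawn uniformly from
    ``lorey_range`` and a target AGB density ``a L^b`` perturbed by
    multiplicative lognormal scatter of the given relative sd.  The tree
    list is built of identical stems (height = L, so Lorey's height is
    exact) whose diameters solve the tree biomass equation for the target
    plot total; all DBH respect the 5 cm census threshold.
    """
    if n_plots < 2:
        raise ValueError("need at least 2 plots")
    if scatter < 0:
        raise ValueError("scatter must be nonnegative")
    rng = np.random.default_rng(seed)
    plots: list[TreePlot] = []
    for i in range(n_plots):
        lorey = rng.uniform(*lorey_range)
        agb = model.a * lorey**model.b
        if scatter > 0:
            agb *= np.exp(rng.normal(0.0, scatter))
        total_kg = agb * area_ha * 1000.0
        n_trees = int(rng.integers(12, 36))
        # keep DBH at or above the census threshold: shrink the tree count
        # until the implied per-tree biomass allows DBH >= 5 cm
        w_min = TREE_AGB_COEF * (5.0**2 * lorey) ** TREE_AGB_EXP
        n_trees = max(1, min(n_trees, int(total_kg / w_min)))
        w = total_kg / n_trees
        d2h = (w / TREE_AGB_COEF) ** (1.0 / TREE_AGB_EXP)
        dbh = float(np.sqrt(d2h / lorey))
        trees = tuple(TreeRecord(dbh=dbh, height=float(lorey)) for _ in range(n_trees))
        plots.append(TreePlot(plot_id=f"{region}-{i:03d}", region=region, trees=trees, area_ha=area_ha))
    return plots


def plots_to_pairs(plots: list[TreePlot]) -> tuple[np.ndarray, np.ndarray]:
    """(Lorey's height, AGB density) pairs of a plot list."""
    lorey = np.array([loreys_height(p.trees) for p in plots])
    agb = np.array([plot_agb_density(p) for p in plots])
    return lorey, agb


def plots_to_frame(plots: list[TreePlot]) -> pd.DataFrame:
    """Tree-level long table (one row per stem) for CSV round-tripping."""
    rows = []
    for p in plots:
        for t in p.trees:
            rows.append((p.plot_id, p.region, p.area_ha, t.dbh, t.height))
    return pd.DataFrame(rows, columns=["plot_id", "region", "area_ha", "dbh", "height"])


def frame_to_plots(df: pd.DataFrame) -> list[TreePlot]:
    plots = []
    for (pid, region, area), sub in df.groupby(["plot_id", "region", "area_ha"], sort=True):
        trees = tuple(TreeRecord(dbh=r.dbh, height=r.height) for r in sub.itertuples())
        plots.append(TreePlot(plot_id=str(pid), region=str(region), trees=trees, area_ha=float(area)))
    return plots


# ---------------------------------------------------------------------------
# Validation sites

@dataclass
class SiteData:
    """Validation sites plus the annual series rasters their filters read.

    ``sites`` carries per-site ground truth of each filter criterion in the
    ``expect_*`` columns; the annual stacks are constructed so that exactly
    the intended sites fail the corresponding criterion.
    """

    sites: pd.DataFrame
    ndvi_annual: np.ndarray  # (n_years, rows, cols)
    sar_hh_annual: np.ndarray
    sar_hv_annual: np.ndarray
    agb_map: np.ndarray  # reference AGB raster for the heterogeneity filter


def _buffer_offsets(radius_m: float, pixel_size: float) -> np.ndarray:
    r_px = radius_m / pixel_size
    n = int(np.floor(r_px))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    sel = yy**2 + xx**2 <= r_px**2 + 1e-9
    return np.column_stack([yy[sel], xx[sel]])


def generate_validation_sites(
    scene: SyntheticScene,
    n: int,
    fraction_unstable: float,
    fraction_heterogeneous: float,
    seed: int,
    buffer_m: float = 100.0,
    n_years: int = 10,
) -> SiteData:
    """Construct validation sites with known filter outcomes.

    Pass sites sit on buffers that are fully forested, temporally stable
    (annual fluctuations well inside the thresholds) and homogeneous.  A
    ``fraction_unstable`` of sites is made to fail temporal stability
    (alternating between an NDVI excursion and a SAR excursion), and a
    ``fraction_heterogeneous`` fraction gets a field AGB small enough that
    the buffer sd / field AGB ratio exceeds 0.25.
    """
    for frac in (fraction_unstable, fraction_heterogeneous):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = scene.grid
    offs = _buffer_offsets(buffer_m, g.pixel_size)

    # stable background series: small inter-annual jitter, far below thresholds
    ndvi_map = DEFAULT_RESPONSES["ndvi"](scene.agb_true)
    hh_map = DEFAULT_RESPONSES["lband_hh"](scene.agb_true)
    hv_map = DEFAULT_RESPONSES["lband_hv"](scene.agb_true)
    ndvi_annual = np.stack([ndvi_map + rng.uniform(-0.02, 0.02) for _ in range(n_years)])
    sar_hh = np.stack([hh_map + rng.uniform(-0.4, 0.4) for _ in range(n_years)])
    sar_hv = np.stack([hv_map + rng.uniform(-0.4, 0.4) for _ in range(n_years)])

    # candidate pixels: buffer fully inside the grid, fully forested,
    # homogeneous enough that untouched sites safely pass every criterion
    m = int(np.ceil(buffer_m / g.pixel_size))
    cand_r, cand_c = np.mgrid[m : g.rows - m, m : g.cols - m]
    cand = np.column_stack([cand_r.ravel(), cand_c.ravel()])
    keep = []
    for r, c in cand[rng.permutation(cand.shape[0])]:
        br, bc = r + offs[:, 0], c + offs[:, 1]
        buf = scene.agb_true[br, bc]
        if not scene.forest_mask[br, bc].all():
            continue
        mu, sd = float(buf.mean()), float(buf.std(ddof=1))
        if mu <= 0 or sd <= 0 or sd / mu > 0.15:
            continue
        if keep and np.any(np.max(np.abs(np.array(keep)[:, :2] - (r, c)), axis=1) < 2 * m + 2):
            continue  # keep buffers disjoint so constructed failures stay local
        keep.append((r, c, mu, sd))
        if len(keep) == n:
            break
    if len(keep) < n:
        raise ValueError(f"could not place {n} disjoint forested sites; scene too small")

    n_unstable = int(round(fraction_unstable * n))
    n_hetero = int(round(fraction_heterogeneous * n))
    order = rng.permutation(n)
    # alternate NDVI/SAR failure modes along the unstable list so exactly
    # ceil/floor(n_unstable/2) sites fail each stability criterion
    unstable_mode = {int(sid): ("ndvi" if j % 2 == 0 else "sar") for j, sid in enumerate(order[:n_unstable])}
    hetero_ids = set(order[n_unstable : n_unstable + n_hetero].tolist())

    rows = []
    for i, (r, c, mu, sd) in enumerate(keep):
        br, bc = r + offs[:, 0], c + offs[:, 1]
        exp_ndvi = exp_sar = True
        if i in unstable_mode:
            if unstable_mode[i] == "ndvi":  # NDVI excursion in one year
                ndvi_annual[n_years // 2][br, bc] += 0.30
                exp_ndvi = False
            else:  # SAR excursion in both polarisations
                sar_hh[n_years // 2][br, bc] += 4.0
                sar_hv[n_years // 2][br, bc] += 4.0
                exp_sar = False
        if i in hetero_ids:
            agb_field = 2.0 * sd  # ratio sd / AGB = 0.5 > 0.25
            exp_homog = False
        else:
            agb_field = mu
            exp_homog = True
        rows.append(
            {
                "id": i,
                "x": g.x0 + (c + 0.5) * g.pixel_size,
                "y": g.y0 + (r + 0.5) * g.pixel_size,
                "agb": agb_field,
                "year": 2011 + int(rng.integers(0, 6)),
                "buffer_m": buffer_m,
                "expect_forest_pass": True,
                "expect_ndvi_pass": exp_ndvi,
                "expect_sar_pass": exp_sar,
                "expect_homog_pass": exp_homog,
            }
        )
    sites = pd.DataFrame(rows)
    sites["expect_survive"] = (
        sites.expect_forest_pass & sites.expect_ndvi_pass & sites.expect_sar_pass & sites.expect_homog_pass
    )
    return SiteData(
        sites=sites,
        ndvi_annual=ndvi_annual,
        sar_hh_annual=sar_hh,
        sar_hv_annual=sar_hv,
        agb_map=scene.agb_true,
    )
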