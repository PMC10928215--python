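"""Field-site filtering, validation metrics and map-comparison statistics.

Field sites are screened before use as validation data:

1. at least half of the 100 m buffer around the site must be forest;
2. the buffer-mean annual maximum-NDVI series must be temporally stable
   (fluctuation, max - min over years, strictly below 0.15);
3. both SAR polarisation series must be stable (fluctuation strictly below
   2 dB);
4. the site must be spatially homogeneous: sd of map AGB in the buffer over
   the field AGB at most 0.25 (sites with zero field AGB are excluded with
   a distinct audit code).

Map summaries follow forest-carbon accounting conventions: mean forest AGB,
forest area, total carbon with a biomass-to-carbon fraction of 0.47, AGB
histograms in 10 Mg ha^-1 right-closed bins labelled by their upper edge,
and pooled pixel distribution statistics within 1 km cells around sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agb_model import r2_rmse
from .raster import Grid

CARBON_FRACTION = 0.47

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not_evaluated"


def _buffer_indices(grid: Grid, x: float, y: float, radius_m: float) -> tuple[np.ndarray, np.ndarray] | None:
    row, col = grid.xy_to_rowcol(np.array([x]), np.array([y]))
    r, c = int(row[0]), int(col[0])
    if not grid.contains(np.array([r]), np.array([c]))[0]:
        return None
    n = int(np.floor(radius_m / grid.pixel_size))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    sel = yy**2 + xx**2 <= (radius_m / grid.pixel_size) ** 2 + 1e-9
    br, bc = r + yy[sel], c + xx[sel]
    inside = grid.contains(br, bc)
    return br[inside], bc[inside]


def filter_sites(
    sites: pd.DataFrame,
    forest_mask: np.ndarray,
    ndvi_annual: np.ndarray,
    sar_hh_annual: np.ndarray,
    sar_hv_annual: np.ndarray,
    agb_map: np.ndarray,
    grid: Grid,
    buffer_m: float = 100.0,
    forest_fraction_min: float = 0.5,
    ndvi_fluct_max: float = 0.15,
    sar_fluct_max: float = 2.0,
    heterogeneity_max: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four site-screening criteria; return (survivors, audit).

    The audit table records each criterion's outcome per site
    (pass/fail/not_evaluated) plus a ``survive`` flag and a ``code`` for
    excluded special cases (outside extent, zero field AGB).  Boundary
    handling: forest fraction passes at exactly 0.5; NDVI and SAR
    fluctuations fail at exactly their thresholds only if strictly greater
    or equal is false — i.e. "< 0.15" and "< 2 dB" are strict; the
    heterogeneity ratio passes at exactly 0.25.
    """
    audit_rows = []
    for site in sites.itertuples():
        rec = {
            "id": site.id,
            "forest_fraction": NOT_EVALUATED,
            "ndvi_stable": NOT_EVALUATED,
            "sar_stable": NOT_EVALUATED,
            "homogeneous": NOT_EVALUATED,
            "code": "",
        }
        buf = _buffer_indices(grid, site.x, site.y, buffer_m)
        if buf is None:
            rec["code"] = "OUTSIDE_EXTENT"
            rec["survive"] = False
            audit_rows.append(rec)
            continue
        br, bc = buf

        frac = float(forest_mask[br, bc].mean())
        rec["forest_fraction"] = PASS if frac >= forest_fraction_min else FAIL

        ndvi_series = ndvi_annual[:, br, bc].mean(axis=1)
        rec["ndvi_stable"] = PASS if float(np.ptp(ndvi_series)) < ndvi_fluct_max else FAIL

        hh = sar_hh_annual[:, br, bc].mean(axis=1)
        hv = sar_hv_annual[:, br, bc].mean(axis=1)
        sar_ok = float(np.ptp(hh)) < sar_fluct_max and float(np.ptp(hv)) < sar_fluct_max
        rec["sar_stable"] = PASS if sar_ok else FAIL

        if site.agb <= 0:
            rec["code"] = "ZERO_AGB"
            rec["homogeneous"] = NOT_EVALUATED
            rec["survive"] = False
            audit_rows.append(rec)
            continue
        sd = float(np.std(agb_map[br, bc], ddof=1)) if br.size > 1 else 0.0
        ratio = sd / float(site.agb)
        rec["homogeneous"] = PASS if ratio <= heterogeneity_max else FAIL
        rec["survive"] = all(
            rec[k] == PASS for k in ("forest_fraction", "ndvi_stable", "sar_stable", "homogeneous")
        )
        audit_rows.append(rec)
    audit = pd.DataFrame(audit_rows)
    survivors = sites[sites["id"].isin(audit.loc[audit["survive"], "id"])].reset_index(drop=True)
    return survivors, audit


def site_metrics(
    agb_map: np.ndarray,
    sites: pd.DataFrame,
    grid: Grid,
    aggregation: str = "pixel",
    cell_size_px: int | None = None,
    forest_mask: np.ndarray | None = None,
    r2_mode: str = "pearson",
) -> tuple[float, float]:
    """R^2 and RMSE of the map against field sites.

    ``aggregation='pixel'`` compares the map pixel value at each site;
    ``'cell'`` first averages both map (forest pixels) and sites within
    square cells of ``cell_size_px`` pixels, for coarse-geolocation data.
    """
    row, col = grid.xy_to_rowcol(sites["x"].to_numpy(), sites["y"].to_numpy())
    inside = grid.contains(row, col)
    if aggregation == "pixel":
        pred = np.full(len(sites), np.nan)
        pred[inside] = agb_map[row[inside], col[inside]]
        return r2_rmse(pred, sites["agb"].to_numpy(), r2_mode=r2_mode)
    if aggregation != "cell":
        raise ValueError("aggregation must be 'pixel' or 'cell'")
    if cell_size_px is None:
        raise ValueError("cell aggregation needs cell_size_px")
    f = int(cell_size_px)
    df = sites.loc[inside, ["agb"]].copy()
    df["cell_row"], df["cell_col"] = row[inside] // f, col[inside] // f
    per_cell = df.groupby(["cell_row", "cell_col"])["agb"].mean().reset_index()
    pred = np.full(len(per_cell), np.nan)
    for i, (cr, cc) in enumerate(zip(per_cell["cell_row"], per_cell["cell_col"])):
        block = agb_map[cr * f : (cr + 1) * f, cc * f : (cc + 1) * f]
        sel = np.isfinite(block)
        if forest_mask is not None:
            sel &= forest_mask[cr * f : (cr + 1) * f, cc * f : (cc + 1) * f]
        if sel.any():
            pred[i] = block[sel].mean()
    return r2_rmse(pred, per_cell["agb"].to_numpy(), r2_mode=r2_mode)


def agb_to_carbon(
    agb_map: np.ndarray,
    pixel_area_ha: float,
    carbon_fraction: float = CARBON_FRACTION,
) -> dict[str, float]:
    """Total carbon bookkeeping: per-pixel carbon = AGB x area x fraction.

    Returns total carbon in Pg C, forest area (finite pixels) in ha, and
    mean AGB in Mg ha^-1.
    """
    fin = np.isfinite(agb_map)
    carbon_mg = np.nansum(agb_map[fin] * pixel_area_ha * carbon_fraction)
    return {
        "total_carbon_pg": float(carbon_mg / 1e9),
        "forest_area_ha": float(fin.sum() * pixel_area_ha),
        "mean_agb": float(agb_map[fin].mean()) if fin.any() else float("nan"),
    }


def histogram_10(values: np.ndarray, bin_width: float = 10.0) -> pd.DataFrame:
    """AGB histogram in fixed-width right-closed bins labelled by upper edge.

    Bin "10" holds (0, 10] (zero values fall in the first bin); relative
    frequencies sum to 1 over the finite input values.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        return pd.DataFrame(columns=["bin_upper", "count", "frequency"])
    idx = np.ceil(v / bin_width).astype(int)
    idx[idx < 1] = 1
    uniq, counts = np.unique(idx, return_counts=True)
    return pd.DataFrame(
        {
            "bin_upper": uniq * bin_width,
            "count": counts,
            "frequency": counts / v.size,
        }
    )


def buffered_boxplot_stats(
    maps: dict[str, np.ndarray],
    sites: pd.DataFrame,
    grid: Grid,
    cell_size_m: float = 1000.0,
    forest_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Distribution statistics of each map's forest pixels within the
    square cells (default 1 km) containing the field sites.

    Pixels are pooled across sites per map; quartiles use linear
    interpolation.  Cells with no forest pixels are excluded (logged in the
    ``n_cells_excluded`` column).
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    f = max(1, int(round(cell_size_m / grid.pixel_size)))
    row, col = grid.xy_to_rowcol(sites["x"].to_numpy(), sites["y"].to_numpy())
    inside = grid.contains(row, col)
    cells = sorted(set(zip((row[inside] // f).tolist(), (col[inside] // f).tolist())))
    rows = []
    for name, m in maps.items():
        pooled = []
        excluded = 0
        for cr, cc in cells:
            block = m[cr * f : (cr + 1) * f, cc * f : (cc + 1) * f]
            sel = np.isfinite(block)
            if forest_mask is not None:
                sel &= forest_mask[cr * f : (cr + 1) * f, cc * f : (cc + 1) * f]
            if sel.any():
                pooled.append(block[sel])
            else:
                excluded += 1
        vals = np.concatenate(pooled) if pooled else np.array([])
        rows.append(
            {
                "map": name,
                "median": float(np.percentile(vals, 50)) if vals.size else float("nan"),
                "q1": float(np.percentile(vals, 25)) if vals.size else float("nan"),
                "q3": float(np.percentile(vals, 75)) if vals.size else float("nan"),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "n_pixels": int(vals.size),
                "n_cells_excluded": excluded,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MapSummary:
    """Headline statistics of one AGB map over its forest pixels."""

    mean_agb: float
    forest_area_ha: float
    total_carbon_pg: float
    histogram: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "mean_agb": self.mean_agb,
            "forest_area_ha": self.forest_area_ha,
            "total_carbon_pg": self.total_carbon_pg,
            "histogram": self.histogram.to_dict(orient="list"),
        }


def summarize_map(
    agb_map: np.ndarray,
    pixel_area_ha: float,
    carbon_fraction: float = CARBON_FRACTION,
    bin_width: float = 10.0,
) -> MapSummary:
    """Mean AGB, forest area, total carbon and histogram of a map."""
    carbon = agb_to_carbon(agb_map, pixel_area_ha, carbon_fraction)
    return MapSummary(
        mean_agb=carbon["mean_agb"],
        forest_area_ha=carbon["forest_area_ha"],
        total_carbon_pg=carbon["total_carbon_pg"],
        histogram=histogram_10(agb_map, bin_width=bin_width),
    )
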