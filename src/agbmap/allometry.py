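"""Tree-level biomass, Lorey's height and regional power-law allometry.

The tree biomass model is the generic China equation

    W = 0.1355 * (D^2 H)^0.817        [W in kg, D = DBH in cm, H in m]

Plot AGB density (Mg ha^-1) is the summed tree biomass divided by plot
area.  Lorey's height is the basal-area-weighted mean tree height, which
up-weights large stems and correlates tightly with stand biomass.  Regional
allometries map Lorey's height L to AGB density via a power law
``AGB = a * L^b``; published reference coefficients for northern and
southern China are exposed as :data:`NORTH_MODEL` and :data:`SOUTH_MODEL`.

Fitting uses nonlinear least squares on the original Mg ha^-1 scale
(so the reported RMSE is in Mg ha^-1), initialised from a log-log OLS fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

#: tree biomass equation W = TREE_AGB_COEF * (D^2 H) ** TREE_AGB_EXP, kg
TREE_AGB_COEF = 0.1355
TREE_AGB_EXP = 0.817

#: minimum censused stem diameter, cm
DBH_CENSUS_MIN = 5.0


@dataclass(frozen=True)
class TreeRecord:
    """A single censused stem: DBH in cm (>= 5 cm census threshold), height in m."""

    dbh: float
    height: float

    def __post_init__(self) -> None:
        if self.dbh < DBH_CENSUS_MIN:
            raise ValueError(f"DBH {self.dbh} cm below census threshold {DBH_CENSUS_MIN} cm")
        if self.height <= 0:
            raise ValueError("tree height must be positive")


@dataclass(frozen=True)
class TreePlot:
    """A fixed-area inventory plot with its tree list.

    ``area_ha`` defaults to 0.05 ha (a 12.5 m-radius circular plot).
    """

    plot_id: str
    region: str
    trees: tuple[TreeRecord, ...]
    area_ha: float = 0.05

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("plot area must be positive")
        if len(self.trees) == 0:
            raise ValueError("plot must contain at least one tree")


@dataclass
class AllometricModel:
    """Power-law allometry AGB = a * Lorey^b for one region.

    ``a`` is in Mg ha^-1 (the AGB of a 1 m Lorey's-height stand), ``b`` is
    dimensionless.  Fit diagnostics are populated by
    :func:`fit_power_allometry` and left None for reference models.
    """

    region: str
    a: float
    b: float
    r2: float | None = None
    rmse: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometric coefficients must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AllometricModel":
        return cls(**json.loads(Path(path).read_text()))


#: Reference regional allometries (Lorey's height in m -> AGB in Mg ha^-1).
NORTH_MODEL = AllometricModel(region="north", a=0.5014, b=1.8762)
SOUTH_MODEL = AllometricModel(region="south", a=0.1237, b=2.3281)
REFERENCE_MODELS: dict[str, AllometricModel] = {"north": NORTH_MODEL, "south": SOUTH_MODEL}


def tree_agb(dbh: float | np.ndarray, height: float | np.ndarray) -> float | np.ndarray:
    """Aboveground biomass of a single tree in kg from DBH (cm) and height (m)."""
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh <= 0) or np.any(height <= 0):
        raise ValueError("DBH and height must be positive")
    out = TREE_AGB_COEF * (dbh**2 * height) ** TREE_AGB_EXP
    return float(out) if out.ndim == 0 else out


def plot_agb_density(plot: TreePlot) -> float:
    """Plot AGB density in Mg ha^-1: summed tree biomass (kg -> Mg) over area."""
    total_kg = sum(tree_agb(t.dbh, t.height) for t in plot.trees)
    return total_kg / 1000.0 / plot.area_ha


def loreys_height(trees: Sequence[TreeRecord] | Iterable[TreeRecord]) -> float:
    """Basal-area-weighted mean height (m); BA_i = pi (D_i/2)^2.

    Only BA ratios matter, so DBH units cancel; result lies in
    [min height, max height] and is invariant to tree order and to uniform
    rescaling of all DBH.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("Lorey's height of an empty tree list is undefined")
    ba = np.array([t.dbh**2 for t in trees])  # pi/4 cancels
    h = np.array([t.height for t in trees])
    return float(np.sum(ba * h) / np.sum(ba))


def fit_power_allometry(
    lorey: Sequence[float],
    agb: Sequence[float],
    region: str = "unlabelled",
) -> AllometricModel:
    """Fit AGB = a * Lorey^b by nonlinear least squares on the original scale.

    Initialised from the log-log OLS solution; diagnostics (R^2 as squared
    Pearson correlation of fitted vs observed, RMSE in Mg ha^-1, n) are
    stored on the returned model.
    """
    x = np.asarray(lorey, dtype=float)
    y = np.asarray(agb, dtype=float)
    if x.size != y.size:
        raise ValueError("lorey and agb must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 (Lorey, AGB) pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("Lorey's height and AGB must be positive for fitting")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all Lorey's heights equal")

    # log-log OLS start values
    b0, loga0 = np.polyfit(np.log(x), np.log(y), 1)
    p0 = (float(np.exp(loga0)), float(b0))
    try:
        popt, _ = curve_fit(lambda L, a, b: a * L**b, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"power-law fit did not converge: {exc}") from exc
    a_hat, b_hat = float(popt[0]), float(popt[1])
    pred = a_hat * x**b_hat
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    r2 = float(np.corrcoef(pred, y)[0, 1] ** 2) if np.ptp(pred) > 0 else float("nan")
    return AllometricModel(region=region, a=a_hat, b=b_hat, r2=r2, rmse=rmse, n=int(x.size))


def predict_agb_from_lorey(model: AllometricModel, lorey: float | np.ndarray) -> float | np.ndarray:
    """AGB density (Mg ha^-1) from Lorey's height (m); 0 maps to 0."""
    lorey_arr = np.asarray(lorey, dtype=float)
    if np.any(lorey_arr < 0):
        raise ValueError("Lorey's height must be nonnegative")
    out = model.a * lorey_arr**model.b
    return float(out) if out.ndim == 0 else out


def invert_lorey_from_agb(model: AllometricModel, agb: float | np.ndarray) -> float | np.ndarray:
    """Inverse allometry: Lorey's height that yields the given AGB density."""
    agb_arr = np.asarray(agb, dtype=float)
    if np.any(agb_arr < 0):
        raise ValueError("AGB must be nonnegative")
    out = (agb_arr / model.a) ** (1.0 / model.b)
    return float(out) if out.ndim == 0 else out
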