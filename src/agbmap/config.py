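"""Pipeline configuration: every tunable threshold and constant, with the
defaults the mapping procedure uses, serializable to/from YAML losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_data import SceneConfig


@dataclass(frozen=True)
class PipelineConfig:
    """All scalar constants of the mapping pipeline.

    Radar calibration and speckle filtering: ``calibration_factor_db`` (the
    L-band mosaic calibration factor), ``focal_radius_m``.  C-band temporal
    statistics need ``min_cband_obs`` observations per pixel.  The forest
    mask uses baseline canopy cover > ``cover_threshold`` % and excludes
    loss up to ``target_year``.  Footprint QC drops slopes >
    ``slope_max`` deg and slopes in (``slope_low``, ``slope_max``] with AGB
    <= ``agb_filter_threshold``; heights are capped at ``height_cap_m``.
    Aggregation keeps cells of ``min_footprints`` footprints or more.  The
    stratified forest splits terrain at ``slope_split`` deg, trains on a
    ``train_frac`` random share of cells with ``n_trees`` trees and prunes
    the ``prune_k`` lowest-importance variables.  Bias correction bins at
    ``bin_width`` Mg ha^-1.  Site screening uses a ``buffer_m`` buffer,
    forest fraction >= 0.5, NDVI fluctuation < ``ndvi_fluct_max``, SAR
    fluctuation < ``sar_fluct_max`` dB and heterogeneity ratio <=
    ``heterogeneity_max``.  Carbon conversion multiplies AGB by
    ``carbon_fraction``.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)

    # sensor preprocessing
    calibration_factor_db: float = -83.0
    focal_radius_m: float = 150.0
    min_cband_obs: int = 2
    include_c_min: bool = True
    cover_threshold: float = 10.0
    target_year: int = 2007

    # footprint processing
    slope_max: float = 15.0
    slope_low: float = 12.0
    agb_filter_threshold: float = 40.0
    height_cap_m: float = 25.0
    min_footprints: int = 2
    cell_average: str = "agb"  # or "height": convert the cell-mean height

    # model
    slope_split: float = 10.0
    train_frac: float = 0.6
    n_trees: int = 500
    prune_k: int = 10
    r2_mode: str = "pearson"

    # bias correction / validation / carbon
    bin_width: float = 10.0
    carbon_fraction: float = 0.47
    buffer_m: float = 100.0
    forest_fraction_min: float = 0.5
    ndvi_fluct_max: float = 0.15
    sar_fluct_max: float = 2.0
    heterogeneity_max: float = 0.25

    # synthetic sampling sizes
    n_footprints: int = 5000
    n_plots_north: int = 26
    n_plots_south: int = 14
    plot_scatter: float = 0.2
    n_sites: int = 20
    fraction_unstable: float = 0.15
    fraction_heterogeneous: float = 0.15

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.cell_average not in ("agb", "height"):
            raise ValueError("cell_average must be 'agb' or 'height'")
        if self.min_footprints < 1 or self.n_trees < 1 or self.prune_k < 0:
            raise ValueError("counts must be positive")

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy of the config with the master seed (and scene seed) replaced."""
        return dataclasses.replace(
            self, seed=seed, scene=dataclasses.replace(self.scene, seed=seed)
        )

    # deterministic sub-seeds for the pipeline's independent random draws
    def subseed(self, offset: int) -> int:
        return (self.seed * 1000 + offset) % (2**31 - 1)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["scene"]["agb_range"] = list(d["scene"]["agb_range"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
        d = yaml.safe_load(text)
        scene = d.pop("scene", {})
        scene["agb_range"] = tuple(scene.get("agb_range", SceneConfig.agb_range))
        return cls(scene=SceneConfig(**scene), **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
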