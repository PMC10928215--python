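"""Planar raster grid and lightweight multi-band TIFF I/O.

Synthetic scenes live in a planar metric frame (metres), so a raster is a
plain 2-D ``float32``/``bool`` numpy array plus a :class:`Grid` describing
pixel size and origin.  Multi-band stacks are written as TIFF files with a
JSON sidecar (``<name>.tif.json``) recording the grid, band names, units and
nodata value; nodata is NaN for float bands.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

NODATA = np.nan


@dataclass(frozen=True)
class Grid:
    """Regular planar grid. ``x0``/``y0`` is the outer corner of pixel (0, 0);
    x grows with column index, y with row index."""

    rows: int
    cols: int
    pixel_size: float = 50.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.rows}x{self.cols}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 1e4

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) centre coordinates as full rasters."""
        r = np.arange(self.rows, dtype=float)
        c = np.arange(self.cols, dtype=float)
        y = self.y0 + (r + 0.5) * self.pixel_size
        x = self.x0 + (c + 0.5) * self.pixel_size
        return np.broadcast_to(y[:, None], self.shape).copy(), np.broadcast_to(x[None, :], self.shape).copy()

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.floor((np.asarray(y) - self.y0) / self.pixel_size).astype(int)
        col = np.floor((np.asarray(x) - self.x0) / self.pixel_size).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)


def write_raster(
    path: str | Path,
    bands: dict[str, np.ndarray],
    grid: Grid,
    units: dict[str, str] | None = None,
) -> None:
    """Write named 2-D bands as a multi-band TIFF plus JSON sidecar."""
    path = Path(path)
    names = list(bands)
    arr = np.stack([np.asarray(bands[n], dtype=np.float32) for n in names])
    for n in names:
        if bands[n].shape != grid.shape:
            raise ValueError(f"band {n!r} shape {bands[n].shape} != grid shape {grid.shape}")
    tifffile.imwrite(path, arr)
    sidecar = {
        "grid": asdict(grid),
        "bands": names,
        "units": units or {},
        "nodata": "nan",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def write_stack(path: str | Path, stack: np.ndarray, grid: Grid, label: str = "") -> None:
    """Write a (n_obs, rows, cols) time stack as a TIFF plus JSON sidecar."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3 or stack.shape[1:] != grid.shape:
        raise ValueError("stack must be (n_obs, rows, cols) on the grid")
    tifffile.imwrite(path, stack)
    sidecar = {"grid": asdict(grid), "stack": stack.shape[0], "label": label, "nodata": "nan"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> tuple[np.ndarray, Grid]:
    meta = json.loads(Path(str(path) + ".json").read_text())
    arr = tifffile.imread(path).astype(np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return arr, Grid(**meta["grid"])


def read_raster(path: str | Path) -> tuple[dict[str, np.ndarray], Grid]:
    """Read a multi-band TIFF written by :func:`write_raster`."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    grid = Grid(**meta["grid"])
    return {n: arr[i].astype(np.float64) for i, n in enumerate(meta["bands"])}, grid
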