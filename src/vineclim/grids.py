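"""Raster container and raster I/O.

The whole pipeline works on a single fixed grid: projected metric coordinates,
square pixels, origin ``(x0, y0)`` at the *lower-left corner* of the raster.
Arrays are stored ``[row, col]`` with row 0 at the southern edge, so
``y = y0 + (row + 0.5) * resolution`` and ``x = x0 + (col + 0.5) * resolution``
give pixel centres.  On-disk formats (ESRI ASCII grid, TIFF) are written
north-up, i.e. flipped relative to the in-memory layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, OutOfBoundsError

#: Fixed covariate ordering used everywhere a design matrix is built.
COVARIATE_NAMES = ("elevation", "slope", "northness", "eastness", "x", "y")


@dataclass
class CovariateGrid:
    """A stack of aligned terrain-covariate layers on one georeferenced grid.

    Layers always include ``elevation`` (m), ``slope`` (percent rise/run),
    ``northness``/``eastness`` (cosine/sine of the downslope azimuth, zero on
    flat pixels), and the projected coordinates ``x``/``y`` (m) of each pixel
    centre.
    """

    x0: float
    y0: float
    resolution: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise InvalidParameterError(f"resolution must be > 0, got {self.resolution}")
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise InvalidParameterError(f"layers disagree on shape: {sorted(shapes)}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def ny(self) -> int:
        return self.shape[0]

    @property
    def nx(self) -> int:
        return self.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.ny * self.nx

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.resolution,
                self.y0 + (row + 0.5) * self.resolution)

    def to_index(self, x: float, y: float) -> tuple[int, int]:
        """Nearest-pixel index for a projected point.

        A point exactly on a pixel boundary is assigned to the lower index
        (documented tie-break, keeps extraction deterministic).
        """
        u = (np.asarray(x, dtype=float) - self.x0) / self.resolution
        v = (np.asarray(y, dtype=float) - self.y0) / self.resolution
        col = np.clip(np.ceil(u).astype(int) - 1, 0, self.nx - 1)
        row = np.clip(np.ceil(v).astype(int) - 1, 0, self.ny - 1)
        # points below the origin are genuinely outside, not clampable
        if np.any(u < 0) or np.any(v < 0) or np.any(u > self.nx) or np.any(v > self.ny):
            raise OutOfBoundsError(f"point ({x}, {y}) outside grid extent")
        return (int(row), int(col)) if np.isscalar(x) else (row, col)

    def contains(self, x: float, y: float) -> bool:
        u = (x - self.x0) / self.resolution
        v = (y - self.y0) / self.resolution
        return 0 <= u <= self.nx and 0 <= v <= self.ny

    # -- design matrices --------------------------------------------------
    def covariate_matrix(self) -> np.ndarray:
        """All pixels as an ``(n_pixels, 6)`` array in :data:`COVARIATE_NAMES` order."""
        return np.column_stack([self.layers[name].ravel() for name in COVARIATE_NAMES])

    def covariates_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [self.layers[name][rows, cols] for name in COVARIATE_NAMES]
        )


# ---------------------------------------------------------------------------
# raster file I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, grid_array: np.ndarray, x0: float, y0: float,
                     resolution: float, nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (plain text, self-georeferenced)."""
    arr = np.asarray(grid_array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"NCOLS {arr.shape[1]}\nNROWS {arr.shape[0]}\n"
        f"XLLCORNER {x0}\nYLLCORNER {y0}\nCELLSIZE {resolution}\n"
        f"NODATA_VALUE {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.4f")  # file rows run north -> south


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns (array south-up, x0, y0, resolution)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.upper()] = float(val)
        arr = np.loadtxt(fh)
    arr = arr.reshape(int(meta["NROWS"]), int(meta["NCOLS"]))[::-1]
    arr[arr == meta["NODATA_VALUE"]] = np.nan
    return arr, meta["XLLCORNER"], meta["YLLCORNER"], meta["CELLSIZE"]


def write_tiff(path: str | Path, grid_array: np.ndarray, x0: float, y0: float,
               resolution: float) -> None:
    """Single-band float32 TIFF plus a JSON georeference sidecar."""
    import tifffile

    arr = np.asarray(grid_array, dtype=np.float32)[::-1]  # north-up on disk
    tifffile.imwrite(str(path), arr)
    sidecar = Path(str(path) + ".aux.json")
    sidecar.write_text(json.dumps(
        {"x0": x0, "y0": y0, "resolution": resolution, "row_order": "north_up"}))


def read_tiff(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    import tifffile

    arr = tifffile.imread(str(path))[::-1].astype(float)
    meta = json.loads(Path(str(path) + ".aux.json").read_text())
    return arr, meta["x0"], meta["y0"], meta["resolution"]
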