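"""Synthetic plateau-and-valley terrain and terrain derivatives.

The generator emulates a low-relief viticultural landscape: limestone
plateaus around 100 m separated by incised valleys a few metres above sea
level, with the steep slopes concentrated on the plateau flanks.  Elevation
is a smoothed Gaussian random field pushed through a sigmoid, which produces
exactly that bimodal hypsometry.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import InvalidParameterError
from ..grids import CovariateGrid


def horn_gradients(elevation: np.ndarray, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 finite-difference gradients (dz/dx eastward, dz/dy northward).

    Arrays are south-up (row 0 = south).  Edge pixels replicate the nearest
    interior value, so a constant-gradient plane yields the exact plane
    gradient everywhere.
    """
    z = np.pad(elevation, 1, mode="edge")
    c = slice(1, -1)
    n, s = slice(2, None), slice(0, -2)   # row offsets (south-up: +1 row = north)
    e, w = slice(2, None), slice(0, -2)   # col offsets
    dzdx = ((z[n, e] + 2 * z[c, e] + z[s, e]) -
            (z[n, w] + 2 * z[c, w] + z[s, w])) / (8 * resolution)
    dzdy = ((z[n, e] + 2 * z[n, c] + z[n, w]) -
            (z[s, e] + 2 * z[s, c] + z[s, w])) / (8 * resolution)
    # edge ring: replicate nearest interior pixel's derivative
    if elevation.shape[0] > 2 and elevation.shape[1] > 2:
        dzdx = np.pad(dzdx[1:-1, 1:-1], 1, mode="edge")
        dzdy = np.pad(dzdy[1:-1, 1:-1], 1, mode="edge")
    return dzdx, dzdy


def slope_aspect(elevation: np.ndarray, resolution: float,
                 flat_tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope (percent) and aspect components from an elevation layer.

    Aspect is the downslope azimuth from north; ``northness = cos(aspect)``,
    ``eastness = sin(aspect)``.  A south-facing slope therefore has
    northness = -1.  Flat pixels get northness = eastness = 0.
    """
    dzdx, dzdy = horn_gradients(elevation, resolution)
    grad = np.hypot(dzdx, dzdy)
    slope_pct = grad * 100.0
    with np.errstate(invalid="ignore", divide="ignore"):
        northness = np.where(grad > flat_tol, -dzdy / grad, 0.0)
        eastness = np.where(grad > flat_tol, -dzdx / grad, 0.0)
    slope_pct = np.where(grad > flat_tol, slope_pct, 0.0)
    return slope_pct, northness, eastness


def covariate_grid_from_elevation(elevation: np.ndarray, x0: float, y0: float,
                                  resolution_m: float) -> CovariateGrid:
    """Derive the full covariate stack from a bare elevation raster."""
    slope_pct, northness, eastness = slope_aspect(elevation, resolution_m)
    ny, nx = elevation.shape
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    return CovariateGrid(
        x0=x0, y0=y0, resolution=resolution_m,
        layers={"elevation": elevation, "slope": slope_pct,
                "northness": northness, "eastness": eastness,
                "x": x0 + (cols + 0.5) * resolution_m,
                "y": y0 + (rows + 0.5) * resolution_m})


def gen_dem(seed: int, nx: int, ny: int, resolution_m: float = 25.0,
            plateau_elev_m: float = 100.0, valley_elev_m: float = 2.0,
            x0: float = 0.0, y0: float = 0.0,
            smooth_sigma_px: float | None = None, relief_gain: float = 3.0) -> CovariateGrid:
    """Generate a covariate grid with plateau/valley terrain.

    Parameters
    ----------
    smooth_sigma_px
        Correlation length of the underlying random field, in pixels
        (default ``min(nx, ny) / 8``); controls valley width.
    relief_gain
        Steepness of the sigmoid mapping the smooth field onto elevation;
        larger values flatten plateaus and valley floors and steepen flanks.
    """
    if nx < 8 or ny < 8:
        raise InvalidParameterError(f"grid must be at least 8x8, got {nx}x{ny}")
    if resolution_m <= 0:
        raise InvalidParameterError(f"resolution must be > 0, got {resolution_m}")
    if plateau_elev_m < valley_elev_m:
        raise InvalidParameterError("plateau_elev_m must be >= valley_elev_m")

    rng = np.random.default_rng(seed)
    sigma = smooth_sigma_px if smooth_sigma_px is not None else min(nx, ny) / 8
    base = gaussian_filter(rng.standard_normal((ny, nx)), sigma=sigma, mode="reflect")
    sd = base.std()
    if sd > 0:
        base = (base - base.mean()) / sd
    elevation = valley_elev_m + (plateau_elev_m - valley_elev_m) / (
        1.0 + np.exp(-relief_gain * base))

    slope_pct, northness, eastness = slope_aspect(elevation, resolution_m)
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    return CovariateGrid(
        x0=x0, y0=y0, resolution=resolution_m,
        layers={
            "elevation": elevation,
            "slope": slope_pct,
            "northness": northness,
            "eastness": eastness,
            "x": x0 + (cols + 0.5) * resolution_m,
            "y": y0 + (rows + 0.5) * resolution_m,
        },
    )
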