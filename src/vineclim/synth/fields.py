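"""Daily true temperature fields over the covariate grid.

Each day's field is ``regional value + amplitude_scale * (linear combination
of standardized covariates + smooth spatial noise)``.  The covariate weights
switch with the weather regime; the load-bearing feature is the sign flip of
the elevation weight for minimum temperature: positive on clear-calm nights
(cold air drains into valleys, plateaus stay warm) and negative on cloudy
nights (ordinary lapse rate wins).  Maximum temperature keeps a negative
elevation weight in every regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..errors import InvalidParameterError
from ..grids import COVARIATE_NAMES, CovariateGrid

VARIABLES = ("tn", "tx")

#: Weights are degC per standard deviation of the covariate at amplitude_scale 1.
#: "noise" is the standard deviation of the smooth spatial noise term.
DEFAULT_FIELD_COEFFS: dict[tuple[str, str], dict[str, float]] = {
    # clear-calm nights: valleys pool cold air -> elevation warms Tn
    ("tn", "clear_calm"): dict(elevation=1.45, slope=0.3, northness=0.2, eastness=0.1,
                               x=-0.3, y=-0.3, noise=0.4),
    # overcast: lapse rate dominates -> elevation cools Tn
    ("tn", "cloudy"): dict(elevation=-1.8, slope=-0.1, northness=0.3, eastness=0.5,
                           x=0.4, y=-0.2, noise=0.5),
    ("tn", "windy"): dict(elevation=-1.2, slope=0.0, northness=0.1, eastness=0.1,
                          x=-0.2, y=-0.1, noise=0.5),
    # Tx: elevation weight negative in every regime
    ("tx", "clear_calm"): dict(elevation=-1.6, slope=0.2, northness=-0.5, eastness=0.2,
                               x=-0.3, y=-0.2, noise=0.5),
    ("tx", "cloudy"): dict(elevation=-1.0, slope=0.0, northness=-0.2, eastness=0.1,
                           x=-0.2, y=-0.1, noise=0.4),
    ("tx", "windy"): dict(elevation=-1.2, slope=0.1, northness=-0.3, eastness=0.1,
                          x=-0.2, y=-0.1, noise=0.4),
}


@dataclass
class TrueFields:
    """Ground-truth daily Tn/Tx grids plus the weather that generated them."""

    grid: CovariateGrid
    weather: pd.DataFrame
    dates: pd.DatetimeIndex
    data: dict[str, np.ndarray]  # var -> (n_days, ny, nx)

    def series_at(self, var: str, row: int, col: int) -> pd.Series:
        return pd.Series(self.data[var][:, row, col], index=self.dates, name=var)

    def pixel_table(self, row: int, col: int) -> pd.DataFrame:
        """Daily tn/tx/tm at one pixel."""
        df = pd.DataFrame({v: self.data[v][:, row, col] for v in VARIABLES},
                          index=self.dates)
        df["tm"] = (df["tn"] + df["tx"]) / 2
        return df

    def spatial_amplitude(self, var: str) -> pd.Series:
        arr = self.data[var].reshape(len(self.dates), -1)
        return pd.Series(arr.max(axis=1) - arr.min(axis=1), index=self.dates)


def standardize_layers(grid: CovariateGrid) -> dict[str, np.ndarray]:
    """Z-score each covariate layer over the grid (zero-variance -> zeros)."""
    out = {}
    for name in COVARIATE_NAMES:
        layer = grid.layers[name]
        sd = layer.std()
        out[name] = (layer - layer.mean()) / sd if sd > 0 else np.zeros_like(layer)
    return out


def gen_true_fields(grid: CovariateGrid, weather: pd.DataFrame,
                    coeffs: dict[tuple[str, str], dict[str, float]] | None = None,
                    seed: int = 0, noise_sigma_px: float | None = None) -> TrueFields:
    """Generate the per-day true Tn and Tx grids.

    ``coeffs`` maps ``(variable, regime)`` to covariate weights plus a
    ``"noise"`` scale; defaults reproduce the regime-dependent structure
    described above.  The smooth noise is a Gaussian-filtered white field
    renormalised to unit standard deviation, so ``noise`` is in degC at
    amplitude_scale 1.
    """
    if weather is None or len(weather) == 0:
        raise InvalidParameterError("weather sequence is empty")
    coeffs = coeffs if coeffs is not None else DEFAULT_FIELD_COEFFS
    rng = np.random.default_rng(seed)
    std = standardize_layers(grid)
    ny, nx = grid.shape
    sigma = noise_sigma_px if noise_sigma_px is not None else max(2.0, min(nx, ny) / 12)

    dates = pd.DatetimeIndex(weather["date"])
    data = {v: np.empty((len(weather), ny, nx)) for v in VARIABLES}

    for i, day in enumerate(weather.itertuples(index=False)):
        for var in VARIABLES:
            w = coeffs[(var, day.regime)]
            lin = np.zeros((ny, nx))
            for name in COVARIATE_NAMES:
                lin += w.get(name, 0.0) * std[name]
            if w.get("noise", 0.0) > 0:
                noise = gaussian_filter(rng.standard_normal((ny, nx)), sigma=sigma,
                                        mode="reflect")
                sd = noise.std()
                lin += w["noise"] * (noise / sd if sd > 0 else noise)
            regional = day.regional_tn if var == "tn" else day.regional_tx
            data[var][i] = regional + day.amplitude_scale * lin
        # construction constraint: Tn never exceeds Tx anywhere
        data["tx"][i] = np.maximum(data["tx"][i], data["tn"][i])

    return TrueFields(grid=grid, weather=weather.reset_index(drop=True),
                      dates=dates, data=data)
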