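"""Canopy-to-station linear bias correction.

In-canopy thermistors read systematically differently from a standard
weather station (shelter, vegetation, sensor type): daily minima slightly
lower, daily maxima substantially higher.  Because the GFV phenology
thresholds were calibrated on station data, canopy series are mapped onto
the station scale with one ordinary-least-squares affine model per variable
(station as response, canopy as predictor), fitted on paired same-day
QC-passed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError

VARIABLES = ("tn", "tx")
MIN_PAIRED_DAYS = 30


@dataclass(frozen=True)
class CorrectionModel:
    variable: str
    slope: float
    intercept: float
    r2: float
    n: int
    rmse_C: float

    def apply(self, values: np.ndarray | pd.Series):
        return self.slope * values + self.intercept

    def invert(self, values: np.ndarray | pd.Series):
        return (values - self.intercept) / self.slope


def fit_correction(canopy: pd.Series, station: pd.Series, variable: str
                   ) -> CorrectionModel:
    """OLS fit ``station = slope * canopy + intercept`` on paired days.

    Both series must be indexed by date; only days present and finite in
    both are used, and at least 30 such days are required.
    """
    pair = pd.concat({"canopy": canopy, "station": station}, axis=1).dropna()
    if len(pair) < MIN_PAIRED_DAYS:
        raise InsufficientDataError(
            f"{variable}: only {len(pair)} paired days, need >= {MIN_PAIRED_DAYS}")
    res = stats.linregress(pair["canopy"], pair["station"])
    resid = pair["station"] - (res.slope * pair["canopy"] + res.intercept)
    return CorrectionModel(variable=variable, slope=float(res.slope),
                           intercept=float(res.intercept),
                           r2=float(res.rvalue ** 2), n=len(pair),
                           rmse_C=float(np.sqrt(np.mean(resid ** 2))))


def fit_corrections(canopy_daily: pd.DataFrame, station: pd.DataFrame
                    ) -> dict[str, CorrectionModel]:
    """Fit per-variable models from a wide canopy table and a station table.

    ``canopy_daily``: columns (date, tn, tx) — typically the sensor adjacent
    to the station; ``station``: columns (date, tn, tx).
    """
    c = canopy_daily.set_index("date")
    s = station.set_index("date")
    return {var: fit_correction(c[var], s[var], var) for var in VARIABLES}


def apply_correction(daily: pd.DataFrame, models: dict[str, CorrectionModel]
                     ) -> pd.DataFrame:
    """Map a wide daily table (sensor_id?, date, tn, tx) to station scale.

    Tm is recomputed from the corrected tn/tx; the output carries a
    ``corrected = True`` provenance flag.  Affine with positive slope, so
    within-variable day orderings are preserved.
    """
    out = daily.copy()
    for var in VARIABLES:
        if var not in out.columns:
            continue
        if var not in models:
            raise ConfigurationError(f"no correction model for variable '{var}'")
        out[var] = models[var].apply(out[var])
    if "tn" in out.columns and "tx" in out.columns:
        out["tm"] = (out["tn"] + out["tx"]) / 2
    out["corrected"] = True
    return out
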