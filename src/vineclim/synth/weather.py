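"""Daily weather-regime sequence driving the synthetic temperature fields.

Regimes are phenomenological, not physical: each day is classed as
``clear_calm`` (anticyclonic; strong nocturnal cold-air pooling, large
spatial amplitude), ``cloudy`` (overcast depression; spatial structure
almost erased) or ``windy`` (intermediate mixing).  The ``amplitude_scale``
multiplies the whole spatial component of that day's field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError

REGIMES = ("clear_calm", "cloudy", "windy")

#: (low, high) of the uniform draw of amplitude_scale per regime.  Clear-calm
#: days always exceed cloudy days, mirroring the anticyclonic/overcast contrast.
AMPLITUDE_SCALE_RANGE = {
    "clear_calm": (0.7, 1.3),
    "cloudy": (0.08, 0.25),
    "windy": (0.30, 0.65),
}


def gen_weather(seed: int, year: int = 2018, n_days: int | None = None,
                regime_probs: tuple[float, float, float] = (0.40, 0.35, 0.25),
                mean_tm: float = 12.5, seasonal_amp: float = 7.5,
                diurnal_mean: float = 8.0, diurnal_seasonal: float = 3.0,
                ar_sd: float = 2.5, ar_phi: float = 0.7,
                regional_offset: float = 0.0) -> pd.DataFrame:
    """Simulate one year (or ``n_days``) of regional weather.

    The regional daily mean follows a sinusoidal annual cycle (peak mid-July,
    temperate-maritime amplitude) plus AR(1) synoptic noise; the diurnal range
    is widest in summer and on clear days.  ``regional_offset`` shifts the
    whole year (used to fabricate cold/warm vintages).

    Returns a DataFrame with columns ``date, doy, regime, amplitude_scale,
    regional_tn, regional_tx``.
    """
    if n_days is not None and n_days < 1:
        raise InvalidParameterError("n_days must be >= 1")
    if abs(sum(regime_probs) - 1.0) > 1e-9:
        raise InvalidParameterError("regime probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{year}-01-01", periods=n_days or pd.Timestamp(
        f"{year}-12-31").dayofyear, freq="D")
    doy = dates.dayofyear.to_numpy()

    tm_cycle = mean_tm + seasonal_amp * np.cos(2 * np.pi * (doy - 197) / 365.25)
    syn = np.empty(len(dates))
    syn[0] = rng.normal(0, ar_sd)
    eps = rng.normal(0, ar_sd * np.sqrt(1 - ar_phi**2), len(dates))
    for i in range(1, len(dates)):
        syn[i] = ar_phi * syn[i - 1] + eps[i]
    tm = tm_cycle + syn + regional_offset

    regime = rng.choice(REGIMES, size=len(dates), p=list(regime_probs))
    scale = np.empty(len(dates))
    for name, (lo, hi) in AMPLITUDE_SCALE_RANGE.items():
        mask = regime == name
        scale[mask] = rng.uniform(lo, hi, mask.sum())

    diurnal = diurnal_mean + diurnal_seasonal * np.cos(2 * np.pi * (doy - 197) / 365.25)
    diurnal = diurnal + np.where(regime == "clear_calm", 2.0,
                                 np.where(regime == "cloudy", -2.0, 0.0))
    diurnal = np.clip(diurnal + rng.normal(0, 0.8, len(dates)), 2.0, None)

    return pd.DataFrame({
        "date": dates,
        "doy": doy,
        "regime": regime,
        "amplitude_scale": scale,
        "regional_tn": tm - diurnal / 2,
        "regional_tx": tm + diurnal / 2,
    })
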