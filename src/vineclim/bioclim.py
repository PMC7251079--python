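"""Canopy bioclimatic indices and network amplitude statistics.

The canopy Winkler index (CWI) is the classic Winkler degree-day sum — daily
mean temperatures above 10 degC accumulated from Apr 1 to Oct 31 — computed
from in-canopy sensors rather than a weather station.  Spatial amplitude is
the daily network max minus min of a variable; gap-filled values are
excluded from it because fills are network-derived and would shrink the
range artificially.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd

from .errors import UndefinedResultError

WINKLER_BASE_C = 10.0
WINKLER_WINDOW = ((4, 1), (10, 31))   # Apr 1 - Oct 31, 214 days every year
SEASON_WINDOW = ((4, 1), (9, 30))     # growing season, 183 days


def _window_index(year: int, window=WINKLER_WINDOW) -> pd.DatetimeIndex:
    (m0, d0), (m1, d1) = window
    return pd.date_range(f"{year}-{m0:02d}-{d0:02d}", f"{year}-{m1:02d}-{d1:02d}",
                         freq="D")


def canopy_winkler(tm: pd.Series, year: int | None = None,
                   base_C: float = WINKLER_BASE_C) -> dict:
    """CWI for one sensor-year of daily means.

    Missing days inside the window contribute 0 degree-days; their count is
    reported so callers can reject badly covered sensor-years.  Raises if the
    window is entirely missing.
    """
    if year is None:
        year = int(tm.index[0].year)
    window = _window_index(year)
    vals = tm.reindex(window)
    n_used = int(vals.notna().sum())
    if n_used == 0:
        raise UndefinedResultError(f"no daily means in Apr-Oct window of {year}")
    cwi = float(np.clip(vals - base_C, 0.0, None).sum())
    return {"year": year, "index_name": "cwi", "value": cwi,
            "n_days_used": n_used, "n_days_missing": len(window) - n_used}


def season_stats(daily: pd.DataFrame, year: int | None = None) -> dict:
    """Growing-season (Apr 1 - Sep 30) means of tn, tx and tm for one sensor.

    ``daily`` is a per-sensor frame indexed by date with tn/tx columns (tm is
    derived, never read from the input).
    """
    if year is None:
        year = int(daily.index[0].year)
    window = _window_index(year, SEASON_WINDOW)
    sub = daily.reindex(window)
    if sub["tn"].notna().sum() == 0 and sub["tx"].notna().sum() == 0:
        raise UndefinedResultError(f"no data in growing season of {year}")
    tm = (sub["tn"] + sub["tx"]) / 2
    return {"year": year,
            "season_mean_tn": float(sub["tn"].mean()),
            "season_mean_tx": float(sub["tx"].mean()),
            "season_mean_tm": float(tm.mean()),
            "n_days_used": int(tm.notna().sum())}


def network_indices(daily: pd.DataFrame, eligible: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """CWI and season means for every (eligible) sensor-year of a clean table.

    ``daily`` is the long clean table from QC; ``eligible`` the eligibility
    frame (sensor_id, year, eligible) — when given, ineligible sensor-years
    are skipped.
    """
    from .qc import tm_table

    wide = tm_table(daily)
    wide["year"] = pd.DatetimeIndex(wide["date"]).year
    allowed = None
    if eligible is not None:
        allowed = {(r.sensor_id, r.year) for r in eligible.itertuples() if r.eligible}
    rows = []
    for (sensor, year), g in wide.groupby(["sensor_id", "year"]):
        if allowed is not None and (sensor, year) not in allowed:
            continue
        g = g.set_index("date").sort_index()
        try:
            cwi = canopy_winkler(g["tm"], int(year))
            stats = season_stats(g[["tn", "tx"]], int(year))
        except UndefinedResultError:
            continue
        n_filled = int((daily[(daily["sensor_id"] == sensor)
                              & (daily["source"] == "filled")]).shape[0])
        rows.append({"sensor_id": sensor, "year": int(year), "cwi": cwi["value"],
                     "cwi_days_missing": cwi["n_days_missing"],
                     "n_days_filled": n_filled, **{k: v for k, v in stats.items()
                                                   if k.startswith("season_mean")}})
    return pd.DataFrame(rows)


def daily_amplitude(daily: pd.DataFrame) -> pd.DataFrame:
    """Daily network max - min per variable (filled values excluded).

    Undefined (skipped) when fewer than 2 sensors report a day.
    """
    ok = daily[(daily["qc"] == "pass") & daily["value"].notna()
               & (daily["source"] != "filled")]
    rows = []
    for (date, var), g in ok.groupby(["date", "variable"]):
        n = g["sensor_id"].nunique()
        if n < 2:
            continue
        per_sensor = g.groupby("sensor_id")["value"].mean()
        rows.append((date, var, float(per_sensor.max() - per_sensor.min()), n))
    return pd.DataFrame(rows, columns=["date", "variable", "amplitude", "n_sensors"])


def monthly_amplitude_summary(amplitude: pd.DataFrame) -> pd.DataFrame:
    """Per-month, per-variable mean/sd/quartiles of the daily amplitude."""
    amp = amplitude.copy()
    amp["month"] = pd.DatetimeIndex(amp["date"]).month
    out = (amp.groupby(["month", "variable"])["amplitude"]
           .agg(mean="mean", sd="std", q25=lambda s: s.quantile(0.25),
                median="median", q75=lambda s: s.quantile(0.75), n="count")
           .reset_index())
    out["month_name"] = out["month"].map(lambda m: calendar.month_abbr[m])
    return out
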