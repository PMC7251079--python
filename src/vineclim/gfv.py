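"""Thermal-time prediction of grapevine mid-flowering and mid-veraison (GFV).

The GFV model accumulates daily mean temperatures above a 0 degC base from
the 60th day of the year; a phenological stage occurs on the first day the
cumulative sum reaches a cultivar-specific threshold (for Merlot: 1269
degree-days for mid-flowering, 2636 for mid-veraison).  It is a linear,
uncapped model defined on daily means — no sub-daily interpolation of the
crossing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedResultError

STAGES = ("flowering", "veraison")


@dataclass(frozen=True)
class GFVParams:
    """Thermal-time constants: accumulation start, base, stage thresholds (dd)."""

    start_doy: int = 60
    base_C: float = 0.0
    threshold_flowering: float = 1269.0
    threshold_veraison: float = 2636.0

    def __post_init__(self) -> None:
        if not 1 <= self.start_doy <= 365:
            raise InvalidParameterError("start_doy must be in [1, 365]")
        if not 0 < self.threshold_flowering < self.threshold_veraison:
            raise InvalidParameterError(
                "need 0 < threshold_flowering < threshold_veraison")

    @classmethod
    def merlot(cls) -> "GFVParams":
        return cls()

    def threshold(self, stage: str) -> float:
        return {"flowering": self.threshold_flowering,
                "veraison": self.threshold_veraison}[stage]


def gfv_crossing(tm: np.ndarray, doys: np.ndarray, threshold: float,
                 params: GFVParams = GFVParams.merlot()) -> tuple[int | None, float]:
    """First day the degree-day sum reaches ``threshold`` on an arbitrary series.

    ``tm`` is a daily mean-temperature series aligned with ``doys`` (days may
    extend past a calendar year for open-ended accumulation).  Days before
    ``params.start_doy`` contribute nothing.  Returns ``(doy, cumsum_at_doy)``
    or ``(None, total)`` if the threshold is never reached.
    """
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be > 0, got {threshold}")
    tm = np.asarray(tm, dtype=float)
    doys = np.asarray(doys)
    inc = np.clip(tm - params.base_C, 0.0, None)
    inc = np.where(np.isfinite(inc), inc, 0.0)
    inc = np.where(doys >= params.start_doy, inc, 0.0)
    cum = np.cumsum(inc)
    hit = np.nonzero(cum >= threshold)[0]
    if len(hit) == 0:
        return None, float(cum[-1]) if len(cum) else 0.0
    i = hit[0]
    return int(doys[i]), float(cum[i])


def gfv_date(tm: pd.Series, threshold: float,
             params: GFVParams = GFVParams.merlot()) -> int | None:
    """Stage day-of-year for one calendar year of daily means (NaN gaps add 0).

    ``tm`` must be indexed by date within a single year.  Returns the DOY of
    the threshold crossing, or None if the sum never reaches the threshold by
    Dec 31.
    """
    if not isinstance(tm.index, pd.DatetimeIndex):
        raise InvalidParameterError("tm must have a DatetimeIndex")
    years = tm.index.year.unique()
    if len(years) != 1:
        raise InvalidParameterError(f"tm spans multiple years: {list(years)}")
    doy, _ = gfv_crossing(tm.to_numpy(), tm.index.dayofyear.to_numpy(),
                          threshold, params)
    return doy


def predict_stages(daily: pd.DataFrame, params: GFVParams = GFVParams.merlot()
                   ) -> pd.DataFrame:
    """Predict flowering and veraison DOY per sensor-year from a daily table.

    ``daily`` is long-form with columns sensor_id, date, tm (typically the
    bias-corrected table).  Unreached stages are omitted.
    """
    daily = daily.copy()
    daily["year"] = pd.DatetimeIndex(daily["date"]).year
    out = []
    for (sensor, year), gdf in daily.groupby(["sensor_id", "year"], sort=True):
        tm = gdf.set_index("date")["tm"].sort_index()
        for stage in STAGES:
            doy = gfv_date(tm, params.threshold(stage), params)
            if doy is not None:
                out.append((sensor, year, stage, doy))
    return pd.DataFrame(out, columns=["sensor_id", "year", "stage", "doy"])


def validate_rmse(pred: pd.DataFrame, obs: pd.DataFrame,
                  on: tuple[str, ...] = ("sensor_id", "year", "stage")) -> pd.DataFrame:
    """Per-year/stage and pooled RMSE and mean signed error of predicted DOY.

    Rows that fail to match are counted, never silently dropped.  Signed
    error is prediction minus observation, in days.
    """
    merged = pred.merge(obs, on=list(on), how="inner",
                        suffixes=("_pred", "_obs"))
    if len(merged) == 0:
        raise UndefinedResultError("no matched prediction/observation pairs")
    merged["error"] = merged["doy_pred"] - merged["doy_obs"]

    def _score(g: pd.DataFrame) -> pd.Series:
        return pd.Series({"n": len(g),
                          "rmse_days": float(np.sqrt(np.mean(g["error"] ** 2))),
                          "bias_days": float(np.mean(g["error"]))})

    per = (merged.groupby(["year", "stage"])[["error"]]
           .apply(_score).reset_index())
    pooled = (merged.groupby("stage")[["error"]].apply(_score).reset_index())
    pooled.insert(0, "year", "pooled")
    table = pd.concat([per, pooled], ignore_index=True)
    table.attrs["n_unmatched_pred"] = len(pred) - len(merged)
    table.attrs["n_unmatched_obs"] = len(obs) - len(merged)
    table["n"] = table["n"].astype(int)
    return table
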