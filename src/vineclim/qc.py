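"""Sensor-network quality control and gap filling.

Pipeline order for dual-probe daily records:

1. :func:`screen_network` — per-day, per-variable MAD screening of every
   probe value across the network (robust sigma via the 1.4826 normality
   constant, rejection beyond ``mad_k`` robust sigmas from the daily median);
2. :func:`merge_probes` — average the two probes of a shield when they agree
   within a tolerance, fall back to the surviving probe, flag disagreement;
3. :func:`eligibility` — a sensor-year qualifies for gap filling only with
   less than 30% missing days over the year and less than 20% over the
   growing season (Apr 1 - Sep 30), strict inequalities;
4. :func:`gap_fill` — network-deviation filling: the sensor's mean offset
   from the rest of the network, applied to the network mean on missing days.

Hourly inputs are first reduced by :func:`daily_extremes` using asymmetric
windows: the daily minimum is taken between 18:00 of the previous day and
19:00 of the day, the daily maximum between 06:00 of the day and 07:00 of
the next day.  The daily mean is always derived as (Tn + Tx) / 2, never
stored independently.

Gap-filled values are flagged ``source="filled"`` so spatial-model training
can exclude them while every other consumer keeps them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputFormatError, InvalidParameterError

VARIABLES = ("tn", "tx")


@dataclass
class QCConfig:
    """Constants of the QC chain (all temperatures degC, fractions in [0,1])."""

    mad_constant: float = 1.4826   # MAD -> sigma under normality
    mad_k: float = 3.0             # rejection multiplier on the robust sigma
    probe_merge_tol_C: float = 0.5
    max_missing_year: float = 0.30
    max_missing_season: float = 0.20
    season_start: tuple[int, int] = (4, 1)    # Apr 1
    season_end: tuple[int, int] = (9, 30)     # Sep 30
    min_sensors_mad: int = 5

    def __post_init__(self) -> None:
        for name in ("mad_constant", "mad_k", "probe_merge_tol_C",
                     "max_missing_year", "max_missing_season"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.season_start >= self.season_end:
            raise InvalidParameterError("season must lie within the calendar year")


# ---------------------------------------------------------------------------
# hourly -> daily extremes
# ---------------------------------------------------------------------------

def daily_extremes(hourly: pd.DataFrame, sensor_id: str | None = None) -> pd.DataFrame:
    """Reduce one sensor's hourly series to daily Tn/Tx rows.

    ``hourly`` needs columns (timestamp, value); timestamps must be strictly
    increasing at hour resolution.  A day whose extreme window is not fully
    covered by observations is emitted with ``qc="suspect"`` (its value uses
    whatever hours exist); days with an empty window are omitted.
    """
    if sensor_id is None:
        sensor_id = (hourly["sensor_id"].iloc[0] if "sensor_id" in hourly
                     else "sensor")
    ts = pd.DatetimeIndex(hourly["timestamp"])
    if len(ts) == 0:
        raise InputFormatError("empty hourly table")
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise InputFormatError("hourly timestamps must be strictly increasing")

    s = pd.Series(hourly["value"].to_numpy(), index=ts)
    full = pd.date_range(ts[0].floor("h"), ts[-1].floor("h"), freq="h")
    s = s.reindex(full)

    rows = []
    for day in pd.date_range(ts[0].normalize(), ts[-1].normalize(), freq="D"):
        windows = {
            "tn": (day - pd.Timedelta(hours=6), day + pd.Timedelta(hours=19), "min"),
            "tx": (day + pd.Timedelta(hours=6), day + pd.Timedelta(hours=31), "max"),
        }
        for var, (lo, hi, op) in windows.items():
            window = s.loc[lo:hi]
            n_expected = int((hi - lo) / pd.Timedelta(hours=1)) + 1
            present = window.notna()
            if present.sum() == 0:
                continue
            value = window.min() if op == "min" else window.max()
            qc = "pass" if (len(window) == n_expected and present.all()) else "suspect"
            rows.append((sensor_id, day, var, float(value), "merged", qc))
    return pd.DataFrame(
        rows, columns=["sensor_id", "date", "variable", "value", "source", "qc"])


# ---------------------------------------------------------------------------
# MAD screening
# ---------------------------------------------------------------------------

def mad_bounds(values: np.ndarray, cfg: QCConfig = QCConfig()
               ) -> tuple[float, float, float]:
    """(median, lower bound, upper bound) of the daily MAD rejection rule."""
    values = np.asarray(values, dtype=float)
    m = float(np.median(values))
    mad_star = cfg.mad_constant * float(np.median(np.abs(values - m)))
    return m, m - cfg.mad_k * mad_star, m + cfg.mad_k * mad_star


def mad_flags(values: np.ndarray, cfg: QCConfig = QCConfig()
              ) -> tuple[np.ndarray, str | None]:
    """Deletion mask for one day/variable's pooled probe values.

    Degenerate days (robust sigma exactly 0 with non-identical values) pass
    everything and return a warning instead of deleting on a zero band.
    """
    values = np.asarray(values, dtype=float)
    m, lo, hi = mad_bounds(values, cfg)
    if hi == lo:  # MAD* == 0
        if np.all(values == values[0]):
            return np.zeros(len(values), dtype=bool), None
        return (np.zeros(len(values), dtype=bool),
                "degenerate day: MAD=0 with non-identical values, all passed")
    return (values < lo) | (values > hi), None


def screen_network(obs: pd.DataFrame, cfg: QCConfig = QCConfig()
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Apply the daily MAD screen to a dual-probe observation table.

    ``obs`` columns: sensor_id, date, variable, probe_a, probe_b.  Returns a
    copy with boolean ``del_a``/``del_b`` columns plus a list of warnings.
    Days with fewer than ``min_sensors_mad`` reporting sensors pass untouched
    (logged).
    """
    out = obs.copy()
    out["del_a"] = False
    out["del_b"] = False
    warnings: list[str] = []
    for (date, var), idx in out.groupby(["date", "variable"]).groups.items():
        sub = out.loc[idx]
        if sub["sensor_id"].nunique() < cfg.min_sensors_mad:
            warnings.append(f"{date.date()} {var}: <{cfg.min_sensors_mad} sensors, "
                            "MAD screen skipped")
            continue
        pooled = np.concatenate([sub["probe_a"].to_numpy(), sub["probe_b"].to_numpy()])
        finite = np.isfinite(pooled)
        flags = np.zeros(len(pooled), dtype=bool)
        if finite.sum() >= 2:
            f, warn = mad_flags(pooled[finite], cfg)
            flags[finite] = f
            if warn:
                warnings.append(f"{date.date()} {var}: {warn}")
        n = len(sub)
        out.loc[idx, "del_a"] = flags[:n]
        out.loc[idx, "del_b"] = flags[n:]
    return out, warnings


def merge_probes(screened: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Combine the two probes of each shield into one daily value.

    Both survive and agree within tol -> average (``merged``); both survive
    but disagree -> no value, ``suspect``; one survives -> ``single_probe``;
    none -> ``deleted``.
    """
    a = screened["probe_a"].to_numpy(dtype=float)
    b = screened["probe_b"].to_numpy(dtype=float)
    keep_a = ~screened["del_a"].to_numpy() & np.isfinite(a)
    keep_b = ~screened["del_b"].to_numpy() & np.isfinite(b)

    value = np.full(len(screened), np.nan)
    source = np.full(len(screened), "merged", dtype=object)
    qc = np.full(len(screened), "pass", dtype=object)

    both = keep_a & keep_b
    agree = both & (np.abs(a - b) <= cfg.probe_merge_tol_C)
    disagree = both & ~agree
    only_a = keep_a & ~keep_b
    only_b = keep_b & ~keep_a
    none = ~keep_a & ~keep_b

    value[agree] = (a[agree] + b[agree]) / 2
    value[only_a] = a[only_a]
    value[only_b] = b[only_b]
    source[only_a | only_b] = "single_probe"
    qc[disagree] = "suspect"
    qc[none] = "deleted"
    source[disagree | none] = "none"

    out = screened[["sensor_id", "date", "variable"]].copy()
    out["value"] = value
    out["source"] = source
    out["qc"] = qc
    return out


# ---------------------------------------------------------------------------
# eligibility and gap filling
# ---------------------------------------------------------------------------

def _season_mask(dates: pd.DatetimeIndex, cfg: QCConfig) -> np.ndarray:
    md = list(zip(dates.month, dates.day))
    return np.array([cfg.season_start <= x <= cfg.season_end for x in md])


def eligibility(daily: pd.DataFrame, cfg: QCConfig = QCConfig()) -> pd.DataFrame:
    """Per sensor-year missing fractions and the gap-fill eligibility verdict.

    Missing = calendar days without a ``qc == "pass"`` value; fractions are
    computed per variable and combined by worst case.  Eligible iff the
    yearly fraction is strictly below 30% AND the growing-season fraction
    strictly below 20%.
    """
    daily = daily.copy()
    daily["year"] = pd.DatetimeIndex(daily["date"]).year
    rows = []
    for (sensor, year), g in daily.groupby(["sensor_id", "year"]):
        cal = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        season = _season_mask(cal, cfg)
        worst_year, worst_season = 0.0, 0.0
        for var in VARIABLES:
            ok = g[(g["variable"] == var) & (g["qc"] == "pass") & g["value"].notna()]
            have = cal.isin(pd.DatetimeIndex(ok["date"]))
            fy = 1.0 - have.sum() / len(cal)
            fs = 1.0 - have[season].sum() / season.sum()
            worst_year, worst_season = max(worst_year, fy), max(worst_season, fs)
        rows.append((sensor, year, worst_year, worst_season,
                     bool(worst_year < cfg.max_missing_year
                          and worst_season < cfg.max_missing_season)))
    return pd.DataFrame(rows, columns=[
        "sensor_id", "year", "missing_year", "missing_season", "eligible"])


def gap_fill(daily: pd.DataFrame, sensor_ids: list[str] | None = None,
             cfg: QCConfig = QCConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Network-deviation filling of missing daily values.

    For each sensor and variable, the mean deviation from the network average
    of all *other* reporting sensors (over the sensor's observed days) is
    added to that average on missing days.  Observed ``qc == "pass"`` values
    are never altered.  Returns (rows to append with ``source="filled"``,
    log of unfillable sensor-days).
    """
    targets = sensor_ids if sensor_ids is not None else sorted(daily["sensor_id"].unique())
    filled_rows, unfilled = [], []
    for var in VARIABLES:
        ok = daily[(daily["variable"] == var) & (daily["qc"] == "pass")
                   & daily["value"].notna()]
        wide = ok.pivot_table(index="date", columns="sensor_id", values="value")
        years = pd.DatetimeIndex(wide.index).year.unique() if len(wide) else []
        cal = pd.DatetimeIndex(np.concatenate(
            [pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D").values
             for y in years])) if len(wide) else pd.DatetimeIndex([])
        wide = wide.reindex(cal)
        total = wide.sum(axis=1, skipna=True)
        count = wide.notna().sum(axis=1)
        for sensor in targets:
            if sensor not in wide.columns:
                continue
            col = wide[sensor]
            has_self = col.notna()
            n_others = count - has_self.astype(int)
            others_mean = (total - col.fillna(0.0)) / n_others.replace(0, np.nan)
            usable = has_self & others_mean.notna()
            missing = ~has_self
            if usable.sum() == 0:
                for day in col.index[missing]:
                    unfilled.append((sensor, day, var))
                continue
            delta = float((col[usable] - others_mean[usable]).mean())
            fillable = missing & others_mean.notna()
            for day in col.index[fillable]:
                filled_rows.append((sensor, day, var,
                                    float(others_mean.loc[day] + delta),
                                    "filled", "pass"))
            for day in col.index[missing & ~fillable]:
                unfilled.append((sensor, day, var))
    filled = pd.DataFrame(filled_rows, columns=[
        "sensor_id", "date", "variable", "value", "source", "qc"])
    log = pd.DataFrame(unfilled, columns=["sensor_id", "date", "variable"])
    return filled, log


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def clean_daily(obs: pd.DataFrame, cfg: QCConfig = QCConfig()
                ) -> tuple[pd.DataFrame, dict]:
    """Run screen -> merge -> eligibility -> gap fill on a dual-probe table.

    Returns the clean daily long table (sensor_id, date, variable, value,
    source, qc) including filled rows, and a report dict with per-sensor
    counts and warnings.
    """
    screened, warnings = screen_network(obs, cfg)
    daily = merge_probes(screened, cfg)
    elig = eligibility(daily, cfg)
    eligible_sensors = sorted(elig.loc[elig["eligible"], "sensor_id"].unique())
    filled, unfilled_log = gap_fill(daily, eligible_sensors, cfg)

    # a fill only applies where no observed row exists for that sensor-day-var
    if len(filled):
        key = ["sensor_id", "date", "variable"]
        observed_ok = daily.loc[daily["qc"] == "pass", key]
        filled = (filled.merge(observed_ok.assign(_obs=True), on=key, how="left"))
        filled = filled[filled["_obs"].isna()].drop(columns="_obs")
    if len(filled) == 0:
        filled = pd.DataFrame(columns=daily.columns)
    clean = pd.concat([d for d in (daily, filled) if len(d)],
                      ignore_index=True).sort_values(
        ["sensor_id", "date", "variable"]).reset_index(drop=True)

    per_sensor = {}
    for sensor, g in clean.groupby("sensor_id"):
        per_sensor[sensor] = {
            "deleted": int((g["qc"] == "deleted").sum()),
            "suspect": int((g["qc"] == "suspect").sum()),
            "filled": int((g["source"] == "filled").sum()),
        }
    deleted_probes = int(screened["del_a"].sum() + screened["del_b"].sum())
    report = {
        "per_sensor": per_sensor,
        "deleted_probe_values": deleted_probes,
        "n_filled": int(len(filled)),
        "n_unfillable": int(len(unfilled_log)),
        "eligibility": elig.to_dict(orient="records"),
        "warnings": warnings,
    }
    return clean, report


def tm_table(daily: pd.DataFrame, include_filled: bool = True) -> pd.DataFrame:
    """Wide per sensor-day table with tn, tx and derived tm from pass values."""
    ok = daily[(daily["qc"] == "pass") & daily["value"].notna()]
    if not include_filled:
        ok = ok[ok["source"] != "filled"]
    wide = ok.pivot_table(index=["sensor_id", "date"], columns="variable",
                          values="value").reset_index()
    wide.columns.name = None
    if "tn" in wide and "tx" in wide:
        wide["tm"] = (wide["tn"] + wide["tx"]) / 2
    return wide
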