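"""Hourly series emitter used to exercise the daily-extreme windows.

Emits a piecewise-cosine diurnal cycle anchored at the daily minimum at
06:00 and the daily maximum at 15:00.  With moderate day-to-day changes the
daily-extreme window logic recovers the input tn/tx exactly; that is the
regime the tests use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def emit_hourly(daily: pd.DataFrame, sensor_id: str | None = None) -> pd.DataFrame:
    """Expand a daily (date, tn, tx) table into an hourly temperature series.

    Returns columns (sensor_id?, timestamp, value) with one row per hour from
    the first day's 00:00 to the last day's 23:00.
    """
    daily = daily.sort_values("date").reset_index(drop=True)
    anchors_t, anchors_v = [], []
    for row in daily.itertuples(index=False):
        day = pd.Timestamp(row.date)
        anchors_t += [day + pd.Timedelta(hours=6), day + pd.Timedelta(hours=15)]
        anchors_v += [row.tn, row.tx]
    at = np.array([t.value for t in anchors_t], dtype=float)
    av = np.array(anchors_v, dtype=float)

    start = pd.Timestamp(daily["date"].iloc[0])
    end = pd.Timestamp(daily["date"].iloc[-1]) + pd.Timedelta(hours=23)
    stamps = pd.date_range(start, end, freq="h")
    tt = stamps.view("int64").astype(float)

    idx = np.searchsorted(at, tt, side="right") - 1
    vals = np.empty(len(tt))
    before = idx < 0
    after = idx >= len(at) - 1
    mid = ~(before | after)
    vals[before] = av[0]
    vals[after] = av[-1]
    i = idx[mid]
    frac = (tt[mid] - at[i]) / (at[i + 1] - at[i])
    vals[mid] = av[i] + (av[i + 1] - av[i]) * (1 - np.cos(np.pi * frac)) / 2

    out = pd.DataFrame({"timestamp": stamps, "value": vals})
    if sensor_id is not None:
        out.insert(0, "sensor_id", sensor_id)
    return out
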