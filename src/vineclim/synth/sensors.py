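"""Sensor network sampling, defect injection, and the biased reference station.

Every solar shield carries two thermistor probes; both read the true pixel
value plus independent instrument noise.  Defects are injected on top and
logged exactly once in the :class:`TruthLedger`, which is what lets the QC
stage be scored with real recall / false-deletion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError, OutOfBoundsError
from ..grids import COVARIATE_NAMES, CovariateGrid
from .fields import TrueFields, VARIABLES


@dataclass
class TruthLedger:
    """Ground truth for one synthetic run.

    outlier_log: one row per injected spike (sensor_id, date, variable, probe, offset_C)
    gap_log: one row per withheld sensor-day-variable
    station_bias: per-variable true (slope, intercept) of the station response
    true_pheno: per sensor-year-stage true day of year (noise-free)
    """

    outlier_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    gap_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    station_bias: dict[str, tuple[float, float]] = field(default_factory=dict)
    true_pheno: pd.DataFrame = field(default_factory=pd.DataFrame)


def place_sensors(grid: CovariateGrid, n_sensors: int, seed: int = 0) -> pd.DataFrame:
    """Drop ``n_sensors`` on distinct pixels, uniformly over the grid.

    Returns sensor metadata: id, pixel indices, projected coordinates of the
    pixel centre, and the six terrain covariates at that pixel.
    """
    if n_sensors < 1:
        raise InvalidParameterError("n_sensors must be >= 1")
    if n_sensors > grid.n_pixels:
        raise InvalidParameterError("more sensors than pixels")
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_pixels, size=n_sensors, replace=False)
    rows, cols = np.unravel_index(flat, grid.shape)
    meta = pd.DataFrame({
        "sensor_id": [f"s{i:03d}" for i in range(n_sensors)],
        "row": rows, "col": cols,
    })
    for name in COVARIATE_NAMES:
        meta[name] = grid.layers[name][rows, cols]
    return meta


def sample_sensors(true_fields: TrueFields, meta: pd.DataFrame,
                   probe_sd_C: float = 0.2, outlier_rate: float = 0.01,
                   outlier_min_C: float = 8.0, outlier_max_C: float = 12.0,
                   missing_rate: float = 0.02, seed: int = 0,
                   ledger: TruthLedger | None = None) -> tuple[pd.DataFrame, TruthLedger]:
    """Read the true fields through a defective dual-probe network.

    Per sensor-day-variable: both probes = true pixel value + N(0, probe_sd);
    with probability ``outlier_rate`` one probe also gets a signed spike of
    magnitude in [outlier_min_C, outlier_max_C] (logged); with probability
    ``missing_rate`` the whole sensor-day is withheld (both variables, logged).

    Returns a long observation table (sensor_id, date, variable, probe_a,
    probe_b) and the truth ledger.
    """
    for rate, name in ((outlier_rate, "outlier_rate"), (missing_rate, "missing_rate")):
        if not 0 <= rate <= 1:
            raise InvalidParameterError(f"{name} must be in [0, 1]")
    if outlier_min_C <= 0 or outlier_max_C < outlier_min_C:
        raise InvalidParameterError("need 0 < outlier_min_C <= outlier_max_C")

    grid = true_fields.grid
    bad = meta[(meta["row"] < 0) | (meta["row"] >= grid.ny) |
               (meta["col"] < 0) | (meta["col"] >= grid.nx)]
    if len(bad):
        raise OutOfBoundsError(f"sensors outside grid: {', '.join(bad['sensor_id'])}")

    rng = np.random.default_rng(seed)
    n_days = len(true_fields.dates)
    n_sensors = len(meta)
    rows = meta["row"].to_numpy()
    cols = meta["col"].to_numpy()

    records, outliers, gaps = [], [], []
    missing_day = rng.random((n_sensors, n_days)) < missing_rate
    for si, sensor in enumerate(meta["sensor_id"]):
        for var in VARIABLES:
            truth = true_fields.data[var][:, rows[si], cols[si]]
            a = truth + rng.normal(0, probe_sd_C, n_days)
            b = truth + rng.normal(0, probe_sd_C, n_days)
            spike = rng.random(n_days) < outlier_rate
            for di in np.nonzero(spike)[0]:
                if missing_day[si, di]:
                    continue  # a withheld day cannot also carry a spike
                offset = rng.uniform(outlier_min_C, outlier_max_C) * rng.choice([-1, 1])
                probe = rng.choice(["a", "b"])
                if probe == "a":
                    a[di] += offset
                else:
                    b[di] += offset
                outliers.append((sensor, true_fields.dates[di], var, probe, offset))
            keep = ~missing_day[si]
            records.append(pd.DataFrame({
                "sensor_id": sensor,
                "date": true_fields.dates[keep],
                "variable": var,
                "probe_a": a[keep],
                "probe_b": b[keep],
            }))
            for di in np.nonzero(missing_day[si])[0]:
                gaps.append((sensor, true_fields.dates[di], var))

    obs = pd.concat(records, ignore_index=True)
    ledger = ledger if ledger is not None else TruthLedger()
    ledger.outlier_log = pd.DataFrame(
        outliers, columns=["sensor_id", "date", "variable", "probe", "offset_C"])
    ledger.gap_log = pd.DataFrame(gaps, columns=["sensor_id", "date", "variable"])
    return obs, ledger


def gen_station(true_fields: TrueFields, station_xy: tuple[float, float],
                slope_per_var: dict[str, float] | None = None,
                intercept_per_var: dict[str, float] | None = None,
                noise_sd_C: float = 0.3, seed: int = 0,
                ledger: TruthLedger | None = None) -> tuple[pd.DataFrame, TruthLedger]:
    """Daily series of a reference weather station with a linear offset.

    ``station = slope * canopy_pixel + intercept + noise``.  Defaults plant
    the observed canopy/station contrast: canopy Tn reads slightly below the
    station (intercept +0.2 degC) while canopy Tx reads well above it
    (intercept -1.2 degC), i.e. the Tx gap dominates.
    """
    slope_per_var = slope_per_var if slope_per_var is not None else {"tn": 1.0, "tx": 1.0}
    intercept_per_var = (intercept_per_var if intercept_per_var is not None
                         else {"tn": 0.2, "tx": -1.2})
    grid = true_fields.grid
    if not grid.contains(*station_xy):
        raise OutOfBoundsError(f"station at {station_xy} outside grid extent")
    row, col = grid.to_index(*station_xy)

    rng = np.random.default_rng(seed)
    out = {"date": true_fields.dates}
    for var in VARIABLES:
        canopy = true_fields.data[var][:, row, col]
        out[var] = (slope_per_var[var] * canopy + intercept_per_var[var]
                    + rng.normal(0, noise_sd_C, len(canopy)))
    station = pd.DataFrame(out)
    ledger = ledger if ledger is not None else TruthLedger()
    ledger.station_bias = {v: (slope_per_var[v], intercept_per_var[v]) for v in VARIABLES}
    return station, ledger
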