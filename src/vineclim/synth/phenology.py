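"""Synthetic phenology observations generated by the thermal-time rule.

True stage dates are obtained by running the GFV accumulation on each sensor
pixel's true daily-mean series; observed dates add rounded Gaussian observer
noise.  Because the published GFV thresholds were calibrated on weather-
station temperatures, the generator can optionally transform the canopy-scale
pixel series through the true station bias first, which puts the synthetic
"biology" on the station scale exactly as in the field study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError
from ..gfv import GFVParams, STAGES, gfv_date
from .fields import TrueFields
from .sensors import TruthLedger

#: Default observer noise per stage (days): flowering scored weekly in the
#: field is tighter than veraison, mirroring the validation-error magnitudes.
DEFAULT_OBS_SD_DAYS = {"flowering": 2.2, "veraison": 3.6}


def gen_pheno_obs(true_fields: TrueFields, meta: pd.DataFrame,
                  gfv: GFVParams = GFVParams.merlot(),
                  obs_sd_days: float | dict[str, float] | None = None,
                  seed: int = 0,
                  station_bias: dict[str, tuple[float, float]] | None = None,
                  ledger: TruthLedger | None = None
                  ) -> tuple[pd.DataFrame, TruthLedger]:
    """Generate block phenology observations plus the noise-free truth.

    Each sensor hosts one observation block (block_id = sensor_id).  When
    ``station_bias`` (var -> (slope, intercept)) is given, pixel tn/tx are
    mapped to station scale before accumulation.  Stages whose threshold is
    never reached within the year are absent from both tables (not an error).
    """
    if obs_sd_days is None:
        sd_map = dict(DEFAULT_OBS_SD_DAYS)
    elif isinstance(obs_sd_days, (int, float)):
        if obs_sd_days < 0:
            raise InvalidParameterError("obs_sd_days must be >= 0")
        sd_map = {s: float(obs_sd_days) for s in STAGES}
    else:
        sd_map = {s: float(obs_sd_days[s]) for s in STAGES}
    if any(v < 0 for v in sd_map.values()):
        raise InvalidParameterError("obs_sd_days must be >= 0")

    rng = np.random.default_rng(seed)
    truth_rows, obs_rows = [], []
    years = true_fields.dates.year.unique()

    for sensor, row, col in meta[["sensor_id", "row", "col"]].itertuples(index=False):
        pix = true_fields.pixel_table(row, col)
        if station_bias is not None:
            tn = station_bias["tn"][0] * pix["tn"] + station_bias["tn"][1]
            tx = station_bias["tx"][0] * pix["tx"] + station_bias["tx"][1]
            tm = (tn + tx) / 2
        else:
            tm = pix["tm"]
        for year in years:
            tm_year = tm[tm.index.year == year]
            for stage in STAGES:
                doy = gfv_date(tm_year, gfv.threshold(stage), gfv)
                if doy is None:
                    continue
                truth_rows.append((sensor, int(year), stage, doy))
                noisy = doy + int(round(rng.normal(0, sd_map[stage])))
                obs_rows.append((sensor, sensor, int(year), stage, int(noisy)))

    true_pheno = pd.DataFrame(truth_rows, columns=["sensor_id", "year", "stage", "doy"])
    obs = pd.DataFrame(
        obs_rows, columns=["block_id", "sensor_id", "year", "stage", "doy"])
    ledger = ledger if ledger is not None else TruthLedger()
    ledger.true_pheno = true_pheno
    return obs, ledger
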