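"""One-call construction of a full synthetic study scene.

Bundles terrain, weather, true fields, the defective sensor network, the
biased reference station and phenology observations, with every piece of
ground truth collected in one :class:`TruthLedger`.  Defaults are desk-scale
(a 40x40-pixel grid, 25 sensors, one year); the emulated full deployment is
90 sensors over a ~17x18 km area at 25 m resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..gfv import GFVParams
from ..grids import CovariateGrid
from .fields import TrueFields, gen_true_fields
from .phenology import gen_pheno_obs
from .sensors import TruthLedger, gen_station, place_sensors, sample_sensors
from .terrain import gen_dem
from .weather import gen_weather


@dataclass
class Scene:
    grid: CovariateGrid
    true_fields: TrueFields
    meta: pd.DataFrame
    obs: pd.DataFrame           # dual-probe sensor records
    station: pd.DataFrame
    pheno_obs: pd.DataFrame
    ledger: TruthLedger
    gfv: GFVParams


def simulate_scene(seed: int = 0, nx: int = 40, ny: int = 40,
                   n_sensors: int = 25, years: tuple[int, ...] = (2018,),
                   resolution_m: float = 25.0,
                   probe_sd_C: float = 0.2, outlier_rate: float = 0.01,
                   outlier_min_C: float = 8.0, missing_rate: float = 0.02,
                   station_noise_sd_C: float = 0.3,
                   obs_sd_days: float | dict[str, float] | None = None,
                   regional_offset: float = 0.0,
                   pheno_on_station_scale: bool = True,
                   gfv: GFVParams = GFVParams.merlot()) -> Scene:
    """Generate a complete synthetic deployment with ground truth.

    Sub-seeds are derived deterministically from ``seed`` so regeneration is
    bit-identical.  ``pheno_on_station_scale=True`` computes the true stage
    dates on station-scale temperatures (the scale the GFV thresholds were
    calibrated on); the observations stay canopy-independent either way.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(6) >> 1]  # keep below 2**31

    grid = gen_dem(seeds[0], nx=nx, ny=ny, resolution_m=resolution_m)
    weather = pd.concat(
        [gen_weather(seeds[1] + i, year=y, regional_offset=regional_offset)
         for i, y in enumerate(years)], ignore_index=True)
    tf = gen_true_fields(grid, weather, seed=seeds[2])
    meta = place_sensors(grid, n_sensors, seed=seeds[3])

    ledger = TruthLedger()
    obs, ledger = sample_sensors(
        tf, meta, probe_sd_C=probe_sd_C, outlier_rate=outlier_rate,
        outlier_min_C=outlier_min_C, missing_rate=missing_rate,
        seed=seeds[4], ledger=ledger)

    # station sits mid-grid, on whatever pixel that is
    station_xy = grid.pixel_center(ny // 2, nx // 2)
    station, ledger = gen_station(tf, station_xy, noise_sd_C=station_noise_sd_C,
                                  seed=seeds[5], ledger=ledger)

    pheno_obs, ledger = gen_pheno_obs(
        tf, meta, gfv=gfv, obs_sd_days=obs_sd_days, seed=seeds[5] ^ 0x5EED,
        station_bias=ledger.station_bias if pheno_on_station_scale else None,
        ledger=ledger)

    return Scene(grid=grid, true_fields=tf, meta=meta, obs=obs, station=station,
                 pheno_obs=pheno_obs, ledger=ledger, gfv=gfv)
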