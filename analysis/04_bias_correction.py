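"""Fit the canopy-to-station linear correction and correct the network.

The sensor nearest the station plays the role of the paired canopy logger;
one OLS model per variable maps canopy temperatures onto the station scale
so the station-calibrated phenology thresholds apply.
"""

import json
from dataclasses import asdict
from pathlib import Path

import click
import pandas as pd

import vineclim as vc
from vineclim.grids import read_ascii_grid
from vineclim.synth import covariate_grid_from_elevation


@click.command()
@click.option("--data", default="results/synth", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--clean", default="results/clean_daily.csv", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--out", default="results", show_default=True,
              type=click.Path(path_type=Path))
def main(data: Path, clean: Path, out: Path) -> None:
    daily = pd.read_csv(clean, parse_dates=["date"])
    station = pd.read_csv(data / "station.csv", parse_dates=["date"])
    meta = pd.read_csv(data / "meta.csv")
    elevation, x0, y0, res = read_ascii_grid(data / "dem.asc")
    grid = covariate_grid_from_elevation(elevation, x0, y0, res)

    wide = vc.tm_table(daily)
    cov = vc.extract_at_points(grid, meta)
    srow, scol = grid.to_index(*grid.pixel_center(grid.ny // 2, grid.nx // 2))
    d2 = (cov["row"] - srow) ** 2 + (cov["col"] - scol) ** 2
    anchor = cov.loc[d2.idxmin(), "sensor_id"]
    canopy = wide[wide["sensor_id"] == anchor][["date", "tn", "tx"]]

    models = vc.fit_corrections(canopy, station)
    corrected = vc.apply_correction(wide, models)

    out.mkdir(parents=True, exist_ok=True)
    (out / "correction.json").write_text(json.dumps(
        {v: asdict(m) for v, m in models.items()}, indent=2))
    corrected.to_csv(out / "corrected_daily.csv", index=False)

    for v, m in models.items():
        click.echo(f"{v}: station = {m.slope:.3f} x canopy {m.intercept:+.2f} "
                   f"(r2 {m.r2:.3f}, rmse {m.rmse_C:.2f} degC, n {m.n}, "
                   f"anchor sensor {anchor})")


if __name__ == "__main__":
    main()
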