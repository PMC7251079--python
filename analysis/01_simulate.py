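"""Generate the synthetic study scene and write its data products.

Emulates the deployment the pipeline was built for: a dense canopy
temperature-sensor network over plateau/valley terrain, dual probes with
injected spikes and gaps, a reference weather station with a linear offset,
and block phenology observations.  Ground truth (outlier/gap logs, station
bias, true stage dates) is written alongside so downstream steps can be
scored.
"""

import json
from pathlib import Path

import click

import vineclim as vc
from vineclim.grids import write_ascii_grid


@click.command()
@click.option("--seed", default=1, show_default=True)
@click.option("--nx", default=40, show_default=True)
@click.option("--ny", default=40, show_default=True)
@click.option("--n-sensors", default=25, show_default=True)
@click.option("--out", default="results/synth", show_default=True,
              type=click.Path(path_type=Path))
def main(seed: int, nx: int, ny: int, n_sensors: int, out: Path) -> None:
    scene = vc.simulate_scene(seed=seed, nx=nx, ny=ny, n_sensors=n_sensors)
    out.mkdir(parents=True, exist_ok=True)
    truth = out / "truth"
    truth.mkdir(exist_ok=True)

    scene.obs.to_csv(out / "sensors.csv", index=False)
    meta = scene.meta.copy()
    meta["x"] = [scene.grid.pixel_center(r, c)[0]
                 for r, c in zip(meta["row"], meta["col"])]
    meta["y"] = [scene.grid.pixel_center(r, c)[1]
                 for r, c in zip(meta["row"], meta["col"])]
    meta.to_csv(out / "meta.csv", index=False)
    scene.station.to_csv(out / "station.csv", index=False)
    scene.pheno_obs.to_csv(out / "pheno_obs.csv", index=False)
    write_ascii_grid(out / "dem.asc", scene.grid.layers["elevation"],
                     scene.grid.x0, scene.grid.y0, scene.grid.resolution)

    scene.ledger.outlier_log.to_csv(truth / "outlier_log.csv", index=False)
    scene.ledger.gap_log.to_csv(truth / "gap_log.csv", index=False)
    scene.ledger.true_pheno.to_csv(truth / "true_pheno.csv", index=False)
    (truth / "station_bias.json").write_text(
        json.dumps(scene.ledger.station_bias, indent=2))

    amp = scene.true_fields.spatial_amplitude("tn")
    click.echo(f"scene: {nx}x{ny} px, {n_sensors} sensors, "
               f"{len(scene.true_fields.dates)} days -> {out}")
    click.echo(f"injected: {len(scene.ledger.outlier_log)} spikes, "
               f"{len(scene.ledger.gap_log)} gap entries")
    click.echo(f"true Tn spatial amplitude: mean {amp.mean():.1f} degC, "
               f"max {amp.max():.1f} degC")


if __name__ == "__main__":
    main()
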