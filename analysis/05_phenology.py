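"""Predict mid-flowering and mid-veraison per sensor and validate them.

Runs the Merlot thermal-time model (1269 / 2636 degree-days above 0 degC
from DOY 60) on the bias-corrected daily means and compares predicted stage
dates with the block observations (RMSE and mean signed error in days).
"""

from pathlib import Path

import click
import pandas as pd

import vineclim as vc


@click.command()
@click.option("--corrected", default="results/corrected_daily.csv",
              show_default=True, type=click.Path(path_type=Path))
@click.option("--pheno-obs", default="results/synth/pheno_obs.csv",
              show_default=True, type=click.Path(path_type=Path))
@click.option("--out", default="results", show_default=True,
              type=click.Path(path_type=Path))
def main(corrected: Path, pheno_obs: Path, out: Path) -> None:
    daily = pd.read_csv(corrected, parse_dates=["date"])
    obs = pd.read_csv(pheno_obs)

    pred = vc.predict_stages(daily[["sensor_id", "date", "tm"]])
    validation = vc.validate_rmse(pred, obs[["sensor_id", "year", "stage", "doy"]])

    out.mkdir(parents=True, exist_ok=True)
    pred.to_csv(out / "pheno_pred.csv", index=False)
    validation.to_csv(out / "pheno_validation.csv", index=False)

    for row in validation[validation["year"] == "pooled"].itertuples():
        click.echo(f"{row.stage}: RMSE {row.rmse_days:.1f} days, "
                   f"bias {row.bias_days:+.1f} days (n={row.n})")


if __name__ == "__main__":
    main()
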