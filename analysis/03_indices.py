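"""Canopy bioclimatic indices and network amplitude statistics.

Per eligible sensor-year: canopy Winkler index (degree-days above 10 degC,
Apr 1 - Oct 31) and growing-season means; per day: the network's spatial
amplitude of Tn and Tx with a monthly summary.
"""

import json
from pathlib import Path

import click
import pandas as pd

import vineclim as vc
from vineclim.bioclim import network_indices


@click.command()
@click.option("--clean", default="results/clean_daily.csv", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--qc-report", default="results/qc_report.json", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--out", default="results", show_default=True,
              type=click.Path(path_type=Path))
def main(clean: Path, qc_report: Path, out: Path) -> None:
    daily = pd.read_csv(clean, parse_dates=["date"])
    elig = pd.DataFrame(json.loads(qc_report.read_text())["eligibility"])

    indices = network_indices(daily, elig)
    amp = vc.daily_amplitude(daily)
    monthly = vc.monthly_amplitude_summary(amp)

    out.mkdir(parents=True, exist_ok=True)
    indices.to_csv(out / "indices.csv", index=False)
    amp.to_csv(out / "amplitude.csv", index=False)
    monthly.to_csv(out / "monthly_amplitude.csv", index=False)

    cwi = indices["cwi"]
    tn_amp = amp[amp["variable"] == "tn"]["amplitude"]
    click.echo(f"CWI over {len(indices)} sensor-years: "
               f"mean {cwi.mean():.0f} dd, spatial spread "
               f"(max-min) {cwi.max() - cwi.min():.0f} dd")
    click.echo(f"daily Tn amplitude: mean {tn_amp.mean():.1f} degC, "
               f"max {tn_amp.max():.1f} degC")


if __name__ == "__main__":
    main()
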