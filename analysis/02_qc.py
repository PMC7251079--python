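"""Clean the raw dual-probe records: MAD screen, merge, eligibility, gap fill.

Writes the clean daily table and a QC report; when the simulation's truth
logs are present, also scores the screen's recall and false-deletion rate.
"""

import json
from pathlib import Path

import click
import pandas as pd

import vineclim as vc


@click.command()
@click.option("--data", default="results/synth", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--out", default="results", show_default=True,
              type=click.Path(path_type=Path))
@click.option("--mad-k", default=3.0, show_default=True)
@click.option("--probe-tol", default=0.5, show_default=True)
def main(data: Path, out: Path, mad_k: float, probe_tol: float) -> None:
    cfg = vc.QCConfig(mad_k=mad_k, probe_merge_tol_C=probe_tol)
    obs = pd.read_csv(data / "sensors.csv", parse_dates=["date"])
    clean, report = vc.clean_daily(obs, cfg)

    out.mkdir(parents=True, exist_ok=True)
    clean.to_csv(out / "clean_daily.csv", index=False)
    (out / "qc_report.json").write_text(json.dumps(report, indent=2, default=str))

    n_pass = int((clean["qc"] == "pass").sum())
    click.echo(f"clean table: {len(clean)} rows, {n_pass} pass, "
               f"{report['deleted_probe_values']} probe values deleted, "
               f"{report['n_filled']} filled")

    outlier_log = data / "truth" / "outlier_log.csv"
    if outlier_log.exists():
        ledger = vc.TruthLedger()
        ledger.outlier_log = pd.read_csv(outlier_log, parse_dates=["date"])
        score = vc.score_mad_screen(obs, ledger, cfg)
        (out / "qc_score.json").write_text(json.dumps(score, indent=2))
        click.echo(f"MAD screen vs truth: recall {score['recall']:.3f}, "
                   f"false-deletion rate {score['false_deletion_rate']:.4f}")


if __name__ == "__main__":
    main()
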