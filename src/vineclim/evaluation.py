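"""Scoring of pipeline stages against a synthetic run's ground truth."""

from __future__ import annotations

import pandas as pd

from .qc import QCConfig, screen_network
from .synth import TruthLedger


def score_mad_screen(obs: pd.DataFrame, ledger: TruthLedger,
                     cfg: QCConfig = QCConfig()) -> dict:
    """Recall and false-deletion rate of the MAD screen vs the outlier log.

    Recall = injected spikes whose probe value was deleted / all injected
    spikes; false-deletion rate = deleted clean probe values / all clean
    probe values.
    """
    screened, _ = screen_network(obs, cfg)
    log = ledger.outlier_log
    key = screened.set_index(["sensor_id", "date", "variable"])
    tp = 0
    for r in log.itertuples():
        row = key.loc[(r.sensor_id, r.date, r.variable)]
        tp += bool(row["del_a"] if r.probe == "a" else row["del_b"])
    fn = len(log) - tp

    deleted = pd.concat([
        screened.loc[screened["del_a"], ["sensor_id", "date", "variable"]].assign(probe="a"),
        screened.loc[screened["del_b"], ["sensor_id", "date", "variable"]].assign(probe="b"),
    ])
    if len(deleted):
        hit = deleted.merge(
            log[["sensor_id", "date", "variable", "probe"]].assign(_true=True),
            how="left", on=["sensor_id", "date", "variable", "probe"])
        fp = int(hit["_true"].isna().sum())
    else:
        fp = 0
    n_clean = 2 * len(screened) - len(log)
    return {"recall": tp / (tp + fn) if tp + fn else float("nan"),
            "false_deletion_rate": fp / n_clean if n_clean else float("nan"),
            "tp": tp, "fn": fn, "fp": fp,
            "n_injected": len(log), "n_clean_values": n_clean}
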