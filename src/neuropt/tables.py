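"""Delimited-text I/O and table validation.

All artifacts are TSV (CSV accepted on read): small, diffable, and
directly loadable with pandas.  ``validate_tables`` checks schema and
value ranges for the three core schemas before anything downstream
consumes a file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lotteries import on_grid
from .synthetic import ChoiceDataset, NeuronSignal

SCHEMAS = {
    "choice": ("p_left", "m_left", "p_right", "m_right", "chose_right"),
    "neural": ("neuron_id", "region", "epoch_id", "trial", "p", "m",
               "rate_spk_per_s"),
    "params": ("neuron_id", "region", "epoch_id", "model", "b", "g", "alpha",
               "delta", "gamma"),
}


def _read(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def read_choice_table(path) -> ChoiceDataset:
    df = _read(path)
    return ChoiceDataset(df, {"source": str(path)})


def write_choice_table(data: ChoiceDataset, path) -> None:
    write_table(data.trials, path)


def read_neural_table(path) -> list[NeuronSignal]:
    """Read a per-trial neural table into one signal per (neuron, epoch)."""
    df = _read(path)
    rate_col = "rate_spk_per_s" if "rate_spk_per_s" in df.columns else "rate"
    if rate_col not in df.columns:
        if {"spike_count", "window_s"} <= set(df.columns):
            df["rate"] = df["spike_count"] / df["window_s"]
            rate_col = "rate"
        else:
            raise ValueError("neural table needs rate_spk_per_s, rate, or "
                             "spike_count + window_s columns")
    signals = []
    for (nid, region, epoch), grp in df.groupby(["neuron_id", "region",
                                                 "epoch_id"], sort=True):
        t = grp.reset_index(drop=True)
        trials = pd.DataFrame({"trial": np.arange(len(t)),
                               "p": t["p"].to_numpy(float),
                               "m": t["m"].to_numpy(float),
                               "rate": t[rate_col].to_numpy(float)})
        signals.append(NeuronSignal(str(nid), str(region), str(epoch), trials))
    return signals


def write_neural_table(signals: list[NeuronSignal], path) -> None:
    frames = []
    for sig in signals:
        t = sig.trials.copy()
        frames.append(pd.DataFrame({
            "neuron_id": sig.neuron_id, "region": sig.region,
            "epoch_id": sig.epoch_id, "trial": t["trial"],
            "p": t["p"], "m": t["m"], "rate_spk_per_s": t["rate"]}))
    write_table(pd.concat(frames, ignore_index=True), path)


@dataclass
class ValidationReport:
    path: str
    schema: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_tables(path, schema: str) -> ValidationReport:
    """Validate a delimited table against one of the core schemas.

    Errors make a file unusable (missing columns, p outside (0, 1],
    nonpositive magnitudes, negative rates, non-binary choices);
    off-grid lotteries are warnings only, since external data need not
    come from the 10 x 10 task grid.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    report = ValidationReport(str(path), schema)
    try:
        df = _read(path)
    except Exception as exc:  # unreadable file is a single hard error
        report.errors.append(f"cannot read table: {exc}")
        return report

    required = [c for c in SCHEMAS[schema]]
    if schema == "neural" and "rate_spk_per_s" not in df.columns:
        if {"spike_count", "window_s"} <= set(df.columns):
            required = [c for c in required if c != "rate_spk_per_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.errors.append(f"missing columns: {missing}")
        return report

    def check_prob(col):
        bad = df.index[(df[col] <= 0) | (df[col] > 1)].tolist()
        for i in bad[:20]:
            report.errors.append(
                f"row {i}: {col}={df.loc[i, col]} outside (0, 1] "
                "(the Prelec weight needs log p finite)")

    def check_pos(col, label):
        bad = df.index[df[col] <= 0].tolist()
        for i in bad[:20]:
            report.errors.append(f"row {i}: {label} {col}={df.loc[i, col]} "
                                 "must be positive")

    if schema == "choice":
        for col in ("p_left", "p_right"):
            check_prob(col)
        for col in ("m_left", "m_right"):
            check_pos(col, "magnitude")
        bad = df.index[~df["chose_right"].isin([0, 1])].tolist()
        for i in bad[:20]:
            report.errors.append(f"row {i}: chose_right must be 0 or 1")
        for i, row in df.iterrows():
            if row["p_left"] > 0 and row["m_left"] > 0 and not on_grid(
                    row["p_left"], row["m_left"]):
                report.warnings.append(f"row {i}: left lottery off the task grid")
            if row["p_right"] > 0 and row["m_right"] > 0 and not on_grid(
                    row["p_right"], row["m_right"]):
                report.warnings.append(f"row {i}: right lottery off the task grid")
    elif schema == "neural":
        check_prob("p")
        check_pos("m", "magnitude")
        rate_col = "rate_spk_per_s" if "rate_spk_per_s" in df.columns else None
        if rate_col:
            bad = df.index[df[rate_col] < 0].tolist()
            for i in bad[:20]:
                report.errors.append(f"row {i}: negative firing rate")
        for i, row in df.iterrows():
            if row["p"] > 0 and row["m"] > 0 and not on_grid(row["p"], row["m"]):
                report.warnings.append(f"row {i}: lottery off the task grid")
    elif schema == "params":
        for col in ("alpha", "delta", "gamma"):
            check_pos(col, "parameter")
        bad = df.index[~df["model"].isin(["EV", "EU", "PT1", "PT2"])].tolist()
        for i in bad[:20]:
            report.errors.append(f"row {i}: unknown model {df.loc[i, 'model']!r}")
    return report
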