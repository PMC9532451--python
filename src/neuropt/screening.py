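"""Epoching and linear pre-screening of single-neuron activity.

Firing rates are taken in 1-s windows stepped every 0.5 s through the
2.5-s cue period (four analysis epochs).  Each neuron-epoch is regressed
on reward probability and magnitude, F = b0 + bp*p + bm*m; signals with
both slopes significantly positive are classified P+M+, both negative
P-M-, anything else "other".  Only P+M+ and P-M- signals carry a
potential value signal and enter model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import NeuronSignal

#: (start, stop) of the four 1-s analysis windows, seconds from cue onset
EPOCH_WINDOWS: dict[str, tuple[float, float]] = {
    "e1": (0.0, 1.0),
    "e2": (0.5, 1.5),
    "e3": (1.0, 2.0),
    "e4": (1.5, 2.5),
}
CUE_PERIOD_S = 2.5


@dataclass
class ScreenResult:
    neuron_id: str
    region: str
    epoch_id: str
    b0: float
    bp: float
    bm: float
    t_p: float
    t_m: float
    p_p: float
    p_m: float
    r2: float
    coding_class: str  # "P+M+", "P-M-" or "other"
    n_trials: int


def epoch_rates(neuron_id: str, region: str, trials: pd.DataFrame,
                spike_times) -> list[NeuronSignal]:
    """Slice spike trains into the four 1-s analysis epochs.

    ``trials`` holds one row per single-cue trial with columns ``p`` and
    ``m``; ``spike_times`` is a same-length sequence of arrays of spike
    times in seconds from cue onset.  Rates are plain counts divided by
    the window length — no smoothing.
    """
    if len(spike_times) != len(trials):
        raise ValueError("one spike-time array per trial is required")
    signals = []
    for epoch_id, (t0, t1) in EPOCH_WINDOWS.items():
        if t1 > CUE_PERIOD_S + 1e-9:
            raise ValueError("epoch window exceeds the cue period")
        width = t1 - t0
        rates = [np.sum((np.asarray(st) >= t0) & (np.asarray(st) < t1)) / width
                 for st in spike_times]
        df = pd.DataFrame({"trial": np.arange(len(trials)),
                           "p": trials["p"].to_numpy(float),
                           "m": trials["m"].to_numpy(float),
                           "rate": np.asarray(rates, dtype=float)})
        signals.append(NeuronSignal(neuron_id, region, epoch_id, df))
    return signals


def screen_signal(sig: NeuronSignal, alpha_level: float = 0.05) -> ScreenResult:
    """OLS of trial firing rate on (1, p, m) and P+M+/P-M- classification."""
    t = sig.trials
    if len(t) < 10:
        raise ValueError("screening needs at least 10 trials")
    p = t["p"].to_numpy(float)
    m = t["m"].to_numpy(float)
    if len(np.unique(p)) < 2 or len(np.unique(m)) < 2:
        raise ValueError("screening needs at least 2 distinct p and m levels")
    y = t["rate"].to_numpy(float)
    X = np.column_stack([np.ones_like(p), p, m])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design: p and m are collinear")
    resid = y - X @ coef
    dof = len(y) - 3
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    bp, bm = coef[1], coef[2]
    sig_p, sig_m = pvals[1] < alpha_level, pvals[2] < alpha_level
    if sig_p and sig_m and bp > 0 and bm > 0:
        cls = "P+M+"
    elif sig_p and sig_m and bp < 0 and bm < 0:
        cls = "P-M-"
    else:
        cls = "other"
    return ScreenResult(sig.neuron_id, sig.region, sig.epoch_id,
                        float(coef[0]), float(bp), float(bm),
                        float(tvals[1]), float(tvals[2]),
                        float(pvals[1]), float(pvals[2]), float(r2), cls,
                        len(t))


def select_signals(signals: list[NeuronSignal],
                   results: list[ScreenResult]) -> list[NeuronSignal]:
    """Keep the P+M+ and P-M- neuron-epochs.

    Each qualifying neuron-epoch remains a separate downstream signal; a
    neuron counts as modulated if any of its epochs qualifies (see
    :func:`modulated_neurons`).
    """
    by_key = {(r.neuron_id, r.epoch_id): r for r in results}
    out = []
    for sig in signals:
        r = by_key.get((sig.neuron_id, sig.epoch_id))
        if r is not None and r.coding_class in ("P+M+", "P-M-"):
            out.append(sig)
    return out


def modulated_neurons(results: list[ScreenResult]) -> set[str]:
    """Neuron ids qualifying (P+M+ or P-M-) in at least one epoch."""
    return {r.neuron_id for r in results
            if r.coding_class in ("P+M+", "P-M-")}


@dataclass
class ContingencyReport:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    warning: str | None = None


def region_proportions(counts: dict[str, tuple[int, int]]) -> ContingencyReport:
    """Pearson chi-square for qualifying proportions across groups.

    ``counts`` maps a group (region, or monkey within a region) to
    (qualifying, total).  Yates continuity correction is applied to 2x2
    tables only, matching standard practice.
    """
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    rows = {k: [q, tot - q] for k, (q, tot) in counts.items()}
    table = pd.DataFrame(rows, index=["qualifying", "other"]).T
    if np.any(table.to_numpy() < 0):
        raise ValueError("qualifying count exceeds total")
    correction = table.shape[0] == 2  # Yates for 2x2 only
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(),
                                                   correction=correction)
    warning = None
    if np.any(expected < 1):
        warning = "expected cell count below 1; chi-square approximation unreliable"
    return ContingencyReport(float(chi2), int(df), float(p), table, warning)


def screen_report(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabulate screening results (one row per neuron-epoch)."""
    return pd.DataFrame([{
        "neuron_id": r.neuron_id, "region": r.region, "epoch_id": r.epoch_id,
        "b0": r.b0, "bp": r.bp, "bm": r.bm, "t_p": r.t_p, "t_m": r.t_m,
        "p_p": r.p_p, "p_m": r.p_m, "r2": r.r2, "class": r.coding_class,
    } for r in results])
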