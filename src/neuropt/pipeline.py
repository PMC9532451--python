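"""End-to-end orchestration: simulate -> fit -> screen -> cluster -> network.

A :class:`RunConfig` (constructed directly or loaded from YAML) fixes
every seed and size; :func:`run_pipeline` executes the stages in
dependency order, writes each stage's table under the run directory and
records a manifest with seeds, package version and output digests, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import choice_matrix_summary, compare_behavior_models, wald_tests
from .clustering import cluster_parameters, cluster_region_mix
from .models import ModelId
from .network import NetworkModel, repeat_recovery, sev_surface
from .neural_fit import compare_region, fit_all_models, fit_table
from .reference import SUBJECTS, cluster_ground_truth
from .screening import screen_report, screen_signal, select_signals
from .synthetic import simulate_choices, simulate_population
from .tables import write_choice_table, write_neural_table, write_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every stochastic stage has its own seed."""

    out_dir: str = "run"
    subject: str = "SUN"              # reference behavioral parameter set
    n_choice_trials: int | None = None  # default: the subject's pooled count
    seed_behavior: int = 1
    seed_neurons: int = 2
    seed_cluster: int = 3
    seed_network: int = 4
    n_starts_behavior: int = 20
    n_starts_neural: int = 100
    # synthetic population: signals per reference cluster template C1/C2/C3
    cluster_counts: tuple[int, int, int] = (130, 78, 25)
    param_jitter: float = 0.1
    trials_per_lottery: int = 1
    # clustering
    k: int = 5
    kmeans_restarts: int = 100
    standardize: bool = True
    # network
    reps_per_pair: int = 4
    n_recovery_reps: int = 100
    stages: tuple[str, ...] = ("behavior", "neurons", "cluster", "network")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cluster_counts", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    outputs: list[Path] = []
    subject = SUBJECTS[config.subject]
    params_df = None
    regions = None

    if "behavior" in config.stages:
        logger.info("stage behavior: simulating and fitting choices")
        n = config.n_choice_trials or subject["n_trials"]
        data = simulate_choices(subject["params"], ModelId.PT2, n,
                                config.seed_behavior)
        write_choice_table(data, out / "choices.tsv")
        fits = compare_behavior_models(data, n_starts=config.n_starts_behavior,
                                       seed=config.seed_behavior)
        rows = []
        for f in fits:
            row = {"model": f.model.value, "k": len(f.free_names),
                   "loglik": f.loglik, "aic": f.aic,
                   "converged": f.converged, **{f"est_{k}": v
                                                for k, v in f.params.items()}}
            if f.converged:
                for w in wald_tests(f):
                    row[f"z_{w.parameter}_vs{w.null:g}"] = w.z
                    row[f"p_{w.parameter}_vs{w.null:g}"] = w.p_value
            rows.append(row)
        write_table(pd.DataFrame(rows), out / "behavior_fits.tsv")
        matrix = choice_matrix_summary(data)
        matrix.to_csv(out / "choice_matrix.csv")
        outputs += [out / "choices.tsv", out / "behavior_fits.tsv",
                    out / "choice_matrix.csv"]

    if "neurons" in config.stages:
        logger.info("stage neurons: simulating, screening and fitting signals")
        templates = [(cluster_ground_truth(name), count, config.param_jitter)
                     for name, count in zip(("C1", "C2", "C3"),
                                            config.cluster_counts)]
        pop = simulate_population(templates, seed=config.seed_neurons,
                                  trials_per_lottery=config.trials_per_lottery)
        write_neural_table(pop.signals, out / "neural.tsv")
        write_table(pop.ground_truth, out / "ground_truth.tsv")
        results = [screen_signal(s) for s in pop.signals]
        write_table(screen_report(results), out / "screen.tsv")
        kept = select_signals(pop.signals, results)
        logger.info("screening kept %d / %d signals", len(kept),
                    len(pop.signals))
        per_signal, best = [], []
        for sig in kept:
            fits, winner = fit_all_models(sig, n_starts=config.n_starts_neural,
                                          seed=config.seed_neurons)
            per_signal.append(fits)
            best.append(winner)
        params_df = fit_table(per_signal, best)
        write_table(params_df, out / "neural_fits.tsv")
        by_region: dict[str, list] = {}
        for fits in per_signal:
            any_fit = next(iter(fits.values()))
            by_region.setdefault(any_fit.region, []).append(fits)
        rows = []
        for region, grp in by_region.items():
            if len(grp) < 2:
                continue
            cmp_ = compare_region(grp, region)
            for _, r in cmp_.ladder.iterrows():
                rows.append({"region": region, "winner": cmp_.winner,
                             **r.to_dict()})
        write_table(pd.DataFrame(rows), out / "region_comparison.tsv")
        outputs += [out / "neural.tsv", out / "screen.tsv",
                    out / "neural_fits.tsv", out / "region_comparison.tsv"]

    net = None
    if "cluster" in config.stages:
        if params_df is None:
            raise RuntimeError("cluster stage requires the neurons stage")
        logger.info("stage cluster: PCA + k-means on PT2 parameters")
        pt2 = params_df[params_df["model"] == "PT2"].reset_index(drop=True)
        model = cluster_parameters(pt2, k=config.k, seed=config.seed_cluster,
                                   n_init=config.kmeans_restarts,
                                   standardize=config.standardize)
        assign = pd.DataFrame({
            "neuron_id": pt2["neuron_id"], "epoch_id": pt2["epoch_id"],
            "cluster": [model.cluster_name(a) for a in model.assignments]})
        write_table(assign, out / "cluster_assignments.tsv")
        write_table(model.means, out / "cluster_means.tsv")
        mix = cluster_region_mix(model, pt2["region"].to_numpy())
        (out / "cluster_region_chi2.json").write_text(json.dumps(
            {"chi2": mix.statistic, "df": mix.df, "p": mix.p_value}, indent=1))
        outputs += [out / "cluster_assignments.tsv", out / "cluster_means.tsv"]
        net = NetworkModel.from_means_table(model.means)

    if "network" in config.stages:
        if net is None:
            raise RuntimeError("network stage requires the cluster stage")
        logger.info("stage network: %d recovery repetitions",
                    config.n_recovery_reps)
        _, clip_frac = sev_surface(net, return_clip_fraction=True)
        logger.info("ReLU clipping fraction on the grid: %.3f", clip_frac)
        rec = repeat_recovery(net, n_reps=config.n_recovery_reps,
                              seed=config.seed_network,
                              reps_per_pair=config.reps_per_pair)
        write_table(rec.samples, out / "recovered_params.tsv")
        summary = {"means": rec.means, "sds": rec.sds,
                   "p_vs_1": rec.tests_vs_1, "n_failed": rec.n_failed,
                   "relu_clip_fraction": clip_frac}
        (out / "recovery_summary.json").write_text(json.dumps(summary, indent=1))
        outputs += [out / "recovered_params.tsv", out / "recovery_summary.json"]

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "outputs": {p.name: _digest(p) for p in outputs if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
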