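"""PCA + k-means clustering of fitted PT2 parameter vectors.

Per-signal parameter vectors (b, g, alpha, delta, gamma) are z-scored,
projected onto the fewest principal components explaining at least 90%
of the variance, and partitioned by k-means (k = 5 by default, many
restarts).  Clusters are renamed in descending size order, so C1 is
always the predominant cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .models import ModelId, neural_response
from .lotteries import grid_arrays
from .screening import ContingencyReport, region_proportions
from scipy import stats

PARAM_COLS = ("b", "g", "alpha", "delta", "gamma")
#: optimizer bounds used to winsorize divergent fits before clustering
WINSOR_BOUNDS = {"alpha": (0.05, 5.0), "delta": (0.05, 5.0), "gamma": (0.05, 5.0)}


@dataclass
class ClusterModel:
    params: pd.DataFrame              # winsorized inputs, one row per signal
    standardize: bool
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    loadings: np.ndarray              # PCA components (rows) x parameters
    explained_variance_ratio: np.ndarray
    n_components: int
    k: int
    assignments: np.ndarray           # cluster index per signal, 0 = C1 (largest)
    means: pd.DataFrame               # cluster, n, share, b, g, alpha, delta, gamma

    def cluster_name(self, idx: int) -> str:
        return f"C{idx + 1}"


def cluster_parameters(param_table: pd.DataFrame, k: int = 5, seed: int = 0,
                       n_init: int = 100, standardize: bool = True,
                       var_threshold: float = 0.90) -> ClusterModel:
    """Cluster per-signal (b, g, alpha, delta, gamma) vectors.

    Parameters are winsorized at the optimizer bounds, z-scored (unless
    ``standardize=False``), reduced by PCA to the fewest components
    whose cumulative explained variance exceeds ``var_threshold``, and
    clustered by k-means with ``n_init`` restarts.  Cluster labels are
    re-ordered by descending size.
    """
    if len(param_table) < k:
        raise ValueError(f"need at least k={k} signals, got {len(param_table)}")
    X = param_table.loc[:, list(PARAM_COLS)].astype(float).copy()
    for col, (lo, hi) in WINSOR_BOUNDS.items():
        X[col] = X[col].clip(lo, hi)

    scaler = StandardScaler(with_mean=True, with_std=standardize)
    Z = scaler.fit_transform(X.to_numpy())
    pca = PCA(n_components=len(PARAM_COLS), random_state=seed)
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_threshold) + 1)
    n_comp = min(n_comp, len(PARAM_COLS))

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(scores[:, :n_comp])

    # relabel in descending cluster-size order (C1 = largest)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assignments = relabel[raw]

    rows = []
    n = len(X)
    for c in range(k):
        mask = assignments == c
        rows.append({"cluster": f"C{c + 1}", "n": int(mask.sum()),
                     "share": float(mask.sum() / n),
                     **{col: float(X.loc[mask, col].mean()) for col in PARAM_COLS}})
    means = pd.DataFrame(rows)
    scale = scaler.scale_ if scaler.scale_ is not None else np.ones(len(PARAM_COLS))
    return ClusterModel(X, standardize, scaler.mean_, scale,
                        pca.components_, pca.explained_variance_ratio_,
                        n_comp, k, assignments, means)


def cluster_summary(model: ClusterModel) -> dict[str, dict]:
    """Per-cluster mean-parameter response surfaces on the lottery grid.

    Each surface is the PT2 response from the cluster's mean parameters,
    normalized to its maximum absolute value for display, with concavity
    diagnostics of u(m) (alpha vs 1) and shape of w(p) (whether it
    crosses the diagonal on (0, 1)).
    """
    gp, gm = grid_arrays()
    out = {}
    for _, row in model.means.iterrows():
        surface = neural_response(ModelId.PT2, gp, gm, row["b"], row["g"],
                                  row["alpha"], row["delta"], row["gamma"])
        peak = np.max(np.abs(surface))
        norm = surface / peak if peak > 0 else surface
        # w crosses the diagonal iff w(p*) = p* for some interior p*:
        # for Prelec, the fixed point is p* = exp(-delta**(1/(1-gamma)))
        # when gamma != 1, which is interior iff gamma != 1.
        gamma, delta, alpha = row["gamma"], row["delta"], row["alpha"]
        s_shaped = not np.isclose(gamma, 1.0)
        out[row["cluster"]] = {
            "n": int(row["n"]), "share": float(row["share"]),
            "params": {c: float(row[c]) for c in PARAM_COLS},
            "surface": norm.reshape(10, 10),
            "utility_concave": bool(alpha < 1),
            "weighting_crosses_diagonal": bool(s_shaped),
            "negative_coding": bool(row["g"] < 0),
        }
    return out


def cluster_region_mix(model: ClusterModel,
                       region_labels) -> ContingencyReport:
    """Chi-square for the cluster x region contingency table."""
    regions = np.asarray(region_labels)
    if len(regions) != len(model.assignments):
        raise ValueError("one region label per clustered signal is required")
    table = pd.crosstab(pd.Series(model.assignments, name="cluster"),
                        pd.Series(regions, name="region"))
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(),
                                                   correction=False)
    warning = ("expected cell count below 1; chi-square approximation unreliable"
               if np.any(expected < 1) else None)
    return ContingencyReport(float(chi2), int(df), float(p), table, warning)
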