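"""k-means phenotype clustering in (PC1, PC2) score space.

Participants are partitioned by Lloyd's algorithm with k-means++ starts
(best of ``n_init`` seeded restarts by within-cluster sum of squares) and the
clusters renumbered deterministically by descending centroid PC1, then PC2 -
so cluster 1 is always the high-level / late-change corner regardless of
restart order.  Cluster summaries are mean adherence curves and baseline
characteristic contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, d) in PC-score units, rows ordered by label
    labels: pd.Series  # participant_id -> cluster in 1..k
    wcss: float
    seed: int
    n_init: int

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def kmeans_fit(
    scores: pd.DataFrame, k: int = 4, n_init: int = 50, seed: int = 0
) -> ClusterModel:
    """Fit k-means on a participant x PC-score table (index = participant_id)."""
    X = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} participants, got {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed,
                algorithm="lloyd")
    raw_labels = km.fit_predict(X)
    cent = km.cluster_centers_
    # deterministic numbering: descending PC1, ties by descending PC2
    order = np.lexsort((-cent[:, 1], -cent[:, 0])) if cent.shape[1] >= 2 else np.argsort(-cent[:, 0])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw_labels], index=scores.index, name="cluster")
    centroids = cent[order]
    return ClusterModel(
        k=k, centroids=centroids, labels=labels, wcss=float(km.inertia_),
        seed=seed, n_init=n_init,
    )


def cluster_adherence_curves(
    model: ClusterModel, curve_values: np.ndarray, participant_ids: list[str]
) -> np.ndarray:
    """Pointwise mean curve per cluster; (k, grid) array ordered by cluster."""
    values = np.atleast_2d(np.asarray(curve_values, dtype=float))
    labels = model.labels.reindex(participant_ids)
    if labels.isna().any():
        missing = [p for p, v in labels.items() if pd.isna(v)]
        raise KeyError(f"participants without cluster labels: {missing}")
    out = np.empty((model.k, values.shape[1]))
    for c in range(1, model.k + 1):
        members = labels.to_numpy() == c
        if not members.any():
            raise ValueError(f"cluster {c} has no member curves")
        out[c - 1] = values[members].mean(axis=0)
    return out


def cluster_profile(
    model: ClusterModel,
    covariates: pd.DataFrame,
    rules: Mapping[str, Callable[[pd.DataFrame], pd.Series]],
) -> pd.DataFrame:
    """Counts and within-cluster percentages of derived baseline categories.

    ``rules`` maps a variable name (e.g. "age_group") to a function deriving a
    category label per participant from the covariate table.  Returns a tidy
    table (variable, category, cluster, count, percent); counts per cluster sum
    to the cluster size within each variable.
    """
    cov = covariates.copy()
    if "participant_id" in cov.columns:
        cov = cov.set_index("participant_id")
    labels = model.labels.reindex(cov.index)
    unmapped = labels.index[labels.isna()].tolist()
    if unmapped:
        raise KeyError(f"participants without cluster labels: {unmapped}")
    sizes = labels.value_counts()
    rows = []
    for variable, rule in rules.items():
        categories = rule(cov)
        if categories.isna().any():
            bad = categories.index[categories.isna()].tolist()
            raise ValueError(f"rule {variable!r} left participants unmapped: {bad}")
        for category in sorted(categories.unique()):
            for c in range(1, model.k + 1):
                count = int(((categories == category) & (labels == c)).sum())
                rows.append({
                    "variable": variable,
                    "category": category,
                    "cluster": c,
                    "count": count,
                    "percent": 100.0 * count / sizes[c],
                })
    return pd.DataFrame(rows)


def silhouette_scan(
    scores: pd.DataFrame, k_range: range = range(2, 9), n_init: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Optional report: mean silhouette score for each candidate k."""
    from sklearn.metrics import silhouette_score

    X = scores.to_numpy(dtype=float)
    rows = []
    for k in k_range:
        if k >= len(X):
            break
        model = kmeans_fit(scores, k=k, n_init=n_init, seed=seed)
        rows.append({
            "k": k,
            "silhouette": float(silhouette_score(X, model.labels.to_numpy())),
            "wcss": model.wcss,
        })
    return pd.DataFrame(rows)
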