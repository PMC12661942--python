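"""Station clustering on the leading ordination axes."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans


def within_cluster_ss(x: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from centroids."""
    wss = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        wss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return wss


def cluster_stations(
    coords: pd.DataFrame,
    k: int,
    seed: int | None = None,
    n_axes: int = 3,
    n_restarts: int = 10,
) -> dict:
    """Ward (D2 merge-cost variant) and k-means clustering of stations on
    the first *n_axes* ordination axes.

    Returns a dict with both label Series, the Ward linkage matrix
    (dendrogram), and the within-cluster sum of squares of each solution.
    """
    x = coords.iloc[:, : min(n_axes, coords.shape[1])].to_numpy(dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of stations ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")

    z = linkage(x, method="ward")
    ward_labels = fcluster(z, t=k, criterion="maxclust")

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km_labels = km.fit_predict(x) + 1

    return {
        "ward": pd.Series(ward_labels, index=coords.index, name="ward"),
        "kmeans": pd.Series(km_labels, index=coords.index, name="kmeans"),
        "linkage": z,
        "wss_ward": within_cluster_ss(x, ward_labels),
        "wss_kmeans": float(km.inertia_),
    }
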