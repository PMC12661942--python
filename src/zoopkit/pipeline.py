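"""End-to-end analysis graph on top of the stage modules.

These functions are the programmatic core behind the CLI subcommands:
imaging quantification, per-marker metabarcoding processing, and the
diversity / ordination / environment-driver battery.
"""

from __future__ import annotations

import pandas as pd

from . import imaging, integration, metabarcoding
from .stats import (
    bray_curtis,
    cluster_stations,
    fit_env_vectors,
    jaccard_matrix,
    nmds,
    passive_vectors,
    pca,
    shannon_by_station,
    sqrt_transform,
)
from .stats.diversity import correlation_heatmap_table
from .stats.ordination import influential_taxa

IMAGING_STREAMS = ("AB", "BV", "BM")
_CURRENCY = {"AB": "abundance", "BV": "biovolume", "BM": "biomass"}


def run_imaging(objects: pd.DataFrame, meta: pd.DataFrame, cf_table=None) -> dict:
    """All three imaging community matrices plus accounting and totals."""
    out = {"matrices": {}, "totals": {}}
    for label, currency in _CURRENCY.items():
        matrix, report = imaging.station_matrix(objects, meta, currency, cf_table)
        out["matrices"][label] = matrix
        out["totals"][label] = imaging.station_totals(matrix)
        out["accounting"] = report
    return out


def run_metabarcoding(tables: dict, metazoan_phyla=None, ranks=("species",)) -> dict:
    """Per-marker chain: singletons -> metazoan filter -> NSRA -> ranks."""
    phyla = metazoan_phyla or metabarcoding.METAZOAN_PHYLA
    out = {"nsra": {}, "reports": {}, "rank_matrices": {}}
    for marker, table in tables.items():
        nsra, report = metabarcoding.process_marker(table, phyla)
        out["nsra"][marker] = nsra
        out["reports"][marker] = report
        out["rank_matrices"][marker] = {
            rank: metabarcoding.aggregate_rank(nsra, rank) for rank in ranks
        }
    return out


def stream_matrices(imaging_result: dict, metab_result: dict) -> dict:
    """The six quantitative streams keyed AB/BV/BM/COI/V4/V9, all as
    stations x lineage-string community matrices."""
    streams = dict(imaging_result["matrices"])
    for marker, nsra in metab_result["nsra"].items():
        mat = nsra.values.copy()
        mat.columns = [nsra.lineages[a] for a in mat.columns]
        mat = mat.T.groupby(level=0).sum().T  # pool ASVs sharing a lineage
        mat.attrs["units"] = f"NSRA ({marker})"
        streams[marker] = mat
    return streams


def taxa_lists(streams: dict) -> dict:
    """Per-method lineage lists for Venn / richness (imaging pooled once)."""
    lists = {}
    for label, matrix in streams.items():
        if label in ("BV", "BM"):
            continue  # same taxon list as AB (same image dataset)
        method = "imaging" if label == "AB" else label
        present = matrix.columns[(matrix > 0).any(axis=0)]
        lists[method] = [str(c) for c in present]
    return lists


def run_analysis(
    streams: dict,
    env: pd.DataFrame,
    seed: int,
    n_perm: int = 999,
    nmds_k: int = 2,
    n_starts: int = 8,
    n_clusters: int = 3,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> dict:
    """The multivariate battery over aligned quantitative streams.

    Every stream matrix must share the same station index as ``env``.
    """
    stations = list(env.index)
    for label, m in streams.items():
        if list(m.index) != stations:
            raise ValueError(
                f"station sets differ: stream {label!r} has {list(m.index)}, "
                f"env has {stations}"
            )

    out: dict = {"streams": {}, "seed": seed}

    # alpha diversity and pairwise structure per stream
    shannon = {}
    jaccard = {}
    for label, matrix in streams.items():
        shannon[label] = shannon_by_station(matrix)
        jaccard[label] = jaccard_matrix(matrix)
    out["shannon"] = pd.DataFrame(shannon)
    out["jaccard"] = jaccard
    out["correlations"] = correlation_heatmap_table(jaccard, shannon)

    # environmental PCA with Shannon vectors added passively
    env_pca = pca(env, scale=True)
    env_pca.passive = passive_vectors(env_pca, out["shannon"])
    env_pca.clusters = pd.DataFrame(
        {
            k: v
            for k, v in cluster_stations(
                env_pca.coords, n_clusters, seed=seed
            ).items()
            if k in ("ward", "kmeans")
        }
    )
    out["pca"] = env_pca

    # per-stream Bray-Curtis nMDS with env vectors and clusters
    for i, (label, matrix) in enumerate(streams.items()):
        diss = bray_curtis(sqrt_transform(matrix))
        ordn = nmds(
            diss, k=nmds_k, n_starts=n_starts, max_iter=max_iter, tol=tol,
            seed=seed + i,
        )
        ordn.vectors = fit_env_vectors(ordn, env, n_perm=n_perm, seed=seed + i)
        cl = cluster_stations(
            ordn.coords, n_clusters, seed=seed + i, n_axes=min(3, nmds_k)
        )
        ordn.clusters = pd.DataFrame({k: cl[k] for k in ("ward", "kmeans")})
        out["streams"][label] = {
            "nmds": ordn,
            "dominant": integration.dominant_taxa(matrix, k=5),
            "influential": influential_taxa(matrix, ordn, k=10),
        }
    return out
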