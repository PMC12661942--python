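"""ASV-table processing: metazoan filter, singleton removal, NSRA, ranks.

The processing chain mirrors the sequence accounting of a multi-marker
zooplankton survey: raw reads -> processed reads -> singleton deletion ->
metazoan filter -> per-station NSRA scaling and merge across size
fractions -> rank-aggregated community matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable, community_matrix
from .taxonomy import RANKS, most_resolved, name_at, parse_lineage, rank_index

#: metazoan phyla named in the survey this pipeline models
METAZOAN_PHYLA = frozenset(
    {
        "Annelida",
        "Arthropoda",
        "Chaetognatha",
        "Chordata",
        "Cnidaria",
        "Ctenophora",
        "Echinodermata",
        "Mollusca",
        "Nemertea",
        "Rotifera",
        "Nematoda",
    }
)


def pct1(part: float, whole: float) -> float:
    """Percentage of *part* in *whole*, rounded to one decimal."""
    if whole == 0:
        return float("nan")
    return round(100.0 * part / whole, 1)


def read_processing_report(raw_reads: int, processed_reads: int) -> dict:
    """Accounting for the bioinformatic processing step of one marker."""
    if raw_reads <= 0:
        raise ValueError("raw read count must be positive")
    if processed_reads < 0 or processed_reads > raw_reads:
        raise ValueError("processed reads must lie in [0, raw reads]")
    return {
        "raw_reads": int(raw_reads),
        "processed_reads": int(processed_reads),
        "pct_processed": pct1(processed_reads, raw_reads),
    }


def filter_metazoa(table: AsvTable, metazoan_phyla=METAZOAN_PHYLA) -> tuple[AsvTable, dict]:
    """Keep ASVs whose phylum is in *metazoan_phyla*; report the accounting.

    Percentages are relative to the input table (reads and ASVs).
    """
    if not metazoan_phyla:
        raise ValueError("metazoan phylum set must not be empty")
    phyla = table.lineages.map(lambda s: parse_lineage(s)["phylum"])
    keep = phyla.isin(set(metazoan_phyla))
    kept = table.subset(table.counts.index[keep.to_numpy()])
    in_reads, in_asvs = table.total_reads, table.n_asvs
    report = {
        "marker": table.marker,
        "input_reads": in_reads,
        "input_asvs": in_asvs,
        "kept_reads": kept.total_reads,
        "kept_asvs": kept.n_asvs,
        "removed_reads": in_reads - kept.total_reads,
        "removed_asvs": in_asvs - kept.n_asvs,
        "pct_reads": pct1(kept.total_reads, in_reads),
        "pct_asvs": pct1(kept.n_asvs, in_asvs),
    }
    return kept, report


def remove_singletons(table: AsvTable, threshold: int = 1) -> tuple[AsvTable, dict]:
    """Drop ASVs whose dataset-wide read total is <= *threshold*."""
    totals = table.counts.sum(axis=1)
    keep = totals > threshold
    kept = table.subset(table.counts.index[keep.to_numpy()])
    report = {
        "marker": table.marker,
        "threshold": threshold,
        "dropped_asvs": int((~keep).sum()),
        "dropped_reads": int(totals[~keep].sum()),
        "kept_asvs": kept.n_asvs,
        "kept_reads": kept.total_reads,
    }
    return kept, report


@dataclass
class NsraMatrix:
    """Merged normalized sequence read abundances for one marker.

    ``values``: stations x ASV reals; ``lineages``: ASV id -> lineage;
    ``report``: one row per (station, fraction) with the original depth,
    the station minimum depth and the applied scale factor.
    """

    marker: str
    values: pd.DataFrame
    lineages: pd.Series = field(repr=False)
    report: pd.DataFrame = field(repr=False)


def nsra_scale_merge(table: AsvTable) -> NsraMatrix:
    """Scale each station's size fractions to the station's minimum depth
    and merge them into one row per station.

    Fractions with zero total reads are excluded with a warning (their
    scale factor is undefined).  Within-fraction read proportions are
    preserved exactly; the merged station total equals
    (number of included fractions) x D_min.
    """
    rows = []
    merged: dict = {}
    for station in table.stations:
        sub = table.counts.xs(station, axis=1, level=0)
        depths = sub.sum(axis=0)
        zero = depths[depths == 0].index.tolist()
        if zero:
            warnings.warn(
                f"[W-NSRA-ZERO] station {station}: dropping zero-depth fractions {zero}",
                stacklevel=2,
            )
            sub = sub.drop(columns=zero)
            depths = depths.drop(zero)
        if depths.empty:
            raise ValueError(f"station {station} has no fraction with positive depth")
        d_min = float(depths.min())
        scale = d_min / depths.astype(float)
        scaled = sub.astype(float).mul(scale, axis=1)
        merged[station] = scaled.sum(axis=1)
        for frac in depths.index:
            rows.append(
                {
                    "station": station,
                    "fraction": frac,
                    "depth": int(depths[frac]),
                    "d_min": d_min,
                    "scale": float(scale[frac]),
                }
            )
    values = pd.DataFrame(merged).T
    values = values.loc[:, values.sum(axis=0) > 0]
    values.index.name = "station"
    return NsraMatrix(
        marker=table.marker,
        values=values,
        lineages=table.lineages.loc[values.columns],
        report=pd.DataFrame(rows),
    )


def _rank_label(lineage: dict, rank: str) -> str:
    """Aggregation label at *rank*; unresolved entries pool under their
    most-resolved parent, e.g. 'Calanoida (unassigned family)'."""
    name = name_at(lineage, rank)
    if name:
        return name
    parent_rank, parent = most_resolved(lineage)
    if parent and rank_index(parent_rank) < rank_index(rank):
        return f"{parent} (unassigned {rank})"
    return f"unassigned-{rank}"


def aggregate_rank(data, rank: str, relative: bool = False) -> pd.DataFrame:
    """Aggregate an NsraMatrix, AsvTable, or lineage-keyed community
    matrix to the named rank.

    Returns a stations x category frame; with ``relative=True`` each row
    is expressed in percent (rows sum to 100).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if isinstance(data, NsraMatrix):
        values, lineages = data.values, data.lineages
        units = f"NSRA ({data.marker})"
    elif isinstance(data, AsvTable):
        values = data.counts.T
        lineages = data.lineages
        units = f"reads ({data.marker})"
    elif isinstance(data, pd.DataFrame):
        values = data
        lineages = pd.Series(list(data.columns), index=data.columns)
        units = data.attrs.get("units", "")
    else:
        raise TypeError(f"cannot aggregate a {type(data).__name__}")

    labels = lineages.map(lambda s: _rank_label(parse_lineage(s), rank))
    agg = values.T.groupby(labels.loc[values.columns].to_numpy()).sum().T
    agg.columns.name = rank
    if relative:
        agg = agg.div(agg.sum(axis=1), axis=0) * 100.0
        units = f"relative {units} (%)"
    return community_matrix(agg, units)


def asv_accumulation(
    table: AsvTable, step: int, n_rep: int = 20, seed: int | None = None
) -> pd.DataFrame:
    """Expected distinct-ASV count vs. reads subsampled without replacement.

    Reads are pooled over all columns.  Each replicate walks the depth
    grid (step, 2*step, ..., total) incrementally, drawing the next
    increment without replacement from the remaining pool, so every
    replicate's curve — and therefore the mean — is monotone
    non-decreasing by construction.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    pool = table.counts.sum(axis=1).to_numpy(dtype=np.int64)
    pool = pool[pool > 0]
    total = int(pool.sum())
    rng = np.random.default_rng(seed)
    depths = list(range(step, total, step)) + [total]
    sums = np.zeros(len(depths))
    for _ in range(n_rep):
        remaining = pool.copy()
        seen = np.zeros(len(pool), dtype=np.int64)
        prev = 0
        for i, depth in enumerate(depths):
            draw = rng.multivariate_hypergeometric(remaining, depth - prev)
            remaining -= draw
            seen += draw
            sums[i] += np.count_nonzero(seen)
            prev = depth
    rows = [
        {"reads": depth, "mean_asvs": sums[i] / n_rep} for i, depth in enumerate(depths)
    ]
    return pd.DataFrame(rows)


def process_marker(
    table: AsvTable,
    metazoan_phyla=METAZOAN_PHYLA,
    singleton_threshold: int = 1,
) -> tuple[NsraMatrix, dict]:
    """Full per-marker chain: singletons -> metazoan filter -> NSRA.

    Returns the merged NSRA matrix and a report dict with the singleton,
    metazoan and scaling accounting (Table-style chain)."""
    nosing, singleton_report = remove_singletons(table, singleton_threshold)
    metaz, metazoan_report = filter_metazoa(nosing, metazoan_phyla)
    nsra = nsra_scale_merge(metaz)
    report = {
        "marker": table.marker,
        "input_reads": table.total_reads,
        "input_asvs": table.n_asvs,
        "singletons": singleton_report,
        "metazoa": metazoan_report,
        "nsra": nsra.report,
    }
    return nsra, report
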