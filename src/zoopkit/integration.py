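"""Cross-method taxon harmonization, Venn overlap and richness tables.

Taxon lists from each method (markers + imaging) are reduced to canonical
presence-absence records.  Records are merged only when their lineage
strings are identical after normalization and synonym mapping: a
family-level record is never folded into a species-level record of the
same family — they stay distinct named categories, as in a method-
comparison Venn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .taxonomy import (
    RANKS,
    format_lineage,
    lineage_depth,
    most_resolved,
    parse_lineage,
    rank_index,
)

METHODS = ("COI", "V4", "V9", "imaging")


@dataclass
class TaxonCatalog:
    """Canonical lineage records with their source methods."""

    records: dict = field(default_factory=dict)  # lineage string -> set of methods
    methods: tuple = METHODS

    @property
    def size(self) -> int:
        return len(self.records)

    def sources(self, lineage: str) -> set:
        return self.records[lineage]


def _normalize_name(name: str, synonyms: dict) -> str:
    name = " ".join(str(name).split())
    return synonyms.get(name, name)


def check_synonyms(synonyms: dict) -> None:
    """Reject chains/conflicts: a synonym target must not itself be mapped."""
    for src, dst in synonyms.items():
        if dst in synonyms and synonyms[dst] != dst:
            raise ValueError(f"conflicting synonym mapping: {src!r} -> {dst!r} -> {synonyms[dst]!r}")


def harmonize(taxa_per_method: dict, synonyms: dict | None = None) -> TaxonCatalog:
    """Merge per-method lineage lists into a :class:`TaxonCatalog`.

    ``taxa_per_method`` maps a method label to an iterable of lineage
    strings.  Names are whitespace-normalized and passed through the
    synonym map rank by rank; identical canonical lineage strings merge.
    """
    synonyms = synonyms or {}
    check_synonyms(synonyms)
    records: dict = {}
    methods = tuple(taxa_per_method)
    for method, lineages in taxa_per_method.items():
        for text in lineages:
            lin = parse_lineage(text)
            canon = {r: _normalize_name(lin[r], synonyms) if lin[r] else "" for r in RANKS}
            if lineage_depth(canon) < 0:
                continue  # fully unresolved entries carry no taxon identity
            key = format_lineage(canon)
            records.setdefault(key, set()).add(method)
    return TaxonCatalog(records=records, methods=methods)


def venn_counts(catalog: TaxonCatalog) -> dict:
    """Counts over every non-empty method subset (2^m - 1 cells).

    Keys are frozensets of method labels; values sum to the catalog size.
    """
    methods = list(catalog.methods)
    counts = {
        frozenset(c): 0
        for r in range(1, len(methods) + 1)
        for c in combinations(methods, r)
    }
    for sources in catalog.records.values():
        key = frozenset(s for s in sources if s in methods)
        if key:
            counts[key] += 1
    return counts


def venn_table(counts: dict) -> pd.DataFrame:
    rows = [
        {"methods": "+".join(sorted(k)), "n_methods": len(k), "count": v}
        for k, v in counts.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["n_methods", "methods"])
        .reset_index(drop=True)
    )


def rank_richness(taxa_per_method: dict, include_unassigned: bool = False) -> pd.DataFrame:
    """Method x rank table of unique named categories.

    A lineage contributes its name at every rank it resolves; unnamed
    (unassigned) entries are excluded unless *include_unassigned*.  Cells
    for ranks a method never resolves hold 0.
    """
    out = {}
    for method, lineages in taxa_per_method.items():
        names = {r: set() for r in RANKS}
        for text in lineages:
            lin = parse_lineage(text)
            for r in RANKS:
                if lin[r]:
                    names[r].add(lin[r])
                elif include_unassigned:
                    parent_rank, parent = most_resolved(lin)
                    if parent and rank_index(parent_rank) < rank_index(r):
                        names[r].add(f"{parent} (unassigned {r})")
        out[method] = {r: len(names[r]) for r in RANKS}
    table = pd.DataFrame(out).T
    table.index.name = "method"
    return table


def species_only(taxa_per_method: dict) -> dict:
    """Restrict each method's list to species-resolved lineages (the
    alternative Venn mode)."""
    return {
        m: [t for t in lins if parse_lineage(t)["species"]]
        for m, lins in taxa_per_method.items()
    }


def potential_overlap(catalog: TaxonCatalog) -> pd.DataFrame:
    """Side table of cross-rank near-matches that were NOT merged: pairs
    where one record's lineage is a strict prefix of another's."""
    keys = list(catalog.records)
    parsed = {k: parse_lineage(k) for k in keys}
    rows = []
    for a, b in combinations(keys, 2):
        la, lb = parsed[a], parsed[b]
        da, db = lineage_depth(la), lineage_depth(lb)
        if da == db:
            continue
        shallow, deep = (a, b) if da < db else (b, a)
        ls, ld = parsed[shallow], parsed[deep]
        depth_s = min(da, db)
        if all(ls[r] == ld[r] for r in RANKS[: depth_s + 1]):
            rows.append({"coarse": shallow, "fine": deep})
    return pd.DataFrame(rows, columns=["coarse", "fine"])


def dominant_taxa(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per-station top-k taxa by relative share (%), remainder as 'other'.

    Ties break lexicographically on the taxon label.  Output is long form:
    station, rank (1..k, then 'other'), taxon, share.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = matrix.div(matrix.sum(axis=1), axis=0) * 100.0
    rows = []
    for station, row in rel.iterrows():
        order = sorted(row.items(), key=lambda kv: (-kv[1], str(kv[0])))
        top = order[:k]
        for i, (taxon, share) in enumerate(top, start=1):
            rows.append({"station": station, "rank": i, "taxon": taxon, "share": share})
        rows.append(
            {
                "station": station,
                "rank": "other",
                "taxon": "other",
                "share": 100.0 - sum(s for _, s in top),
            }
        )
    return pd.DataFrame(rows)
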