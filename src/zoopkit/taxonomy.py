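"""Lineage strings and rank handling shared across modules.

A lineage is serialized as ``p__X;c__Y;o__Z;f__W;g__G;s__S`` where empty
names mark unresolved ranks.  The in-memory form is a plain dict mapping
rank name to taxon name (``""`` when unresolved).
"""

from __future__ import annotations

RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

_PREFIX = {
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}
_PREFIX_TO_RANK = {v: k for k, v in _PREFIX.items()}


def rank_index(rank: str) -> int:
    """Position of *rank* in the canonical rank order (0 = phylum)."""
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def format_lineage(lineage: dict) -> str:
    """Serialize a rank->name dict into the prefixed semicolon form."""
    return ";".join(f"{_PREFIX[r]}{lineage.get(r, '') or ''}" for r in RANKS)


def parse_lineage(text: str) -> dict:
    """Parse a lineage string; tolerant of missing trailing fields."""
    out = {r: "" for r in RANKS}
    if not text or text != text:  # NaN guard
        return out
    for field in str(text).split(";"):
        field = field.strip()
        if len(field) >= 3 and field[:3] in _PREFIX_TO_RANK:
            out[_PREFIX_TO_RANK[field[:3]]] = field[3:].strip()
        elif field:
            raise ValueError(f"malformed lineage field {field!r} in {text!r}")
    return out


def truncate_lineage(lineage: dict, rank: str) -> dict:
    """Blank every rank deeper than *rank*."""
    cut = rank_index(rank)
    return {r: (lineage.get(r, "") if i <= cut else "") for i, r in enumerate(RANKS)}


def name_at(lineage: dict, rank: str) -> str:
    return lineage.get(rank, "")


def most_resolved(lineage: dict) -> tuple[str, str]:
    """Deepest (rank, name) pair with a non-empty name.

    Returns ``("", "")`` for a fully unresolved lineage.
    """
    for rank in reversed(RANKS):
        name = lineage.get(rank, "")
        if name:
            return rank, name
    return "", ""


def lineage_depth(lineage: dict) -> int:
    """Index of the deepest resolved rank, or -1 if none."""
    rank, _ = most_resolved(lineage)
    return rank_index(rank) if rank else -1
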