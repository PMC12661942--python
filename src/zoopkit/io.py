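"""TSV readers/writers for the pipeline's tabular dialects.

All files are tab-separated with optional ``#``-prefixed ``key: value``
metadata header lines.  ASV tables use ``station|fraction`` column labels;
object tables follow the imaging-export dialect (extra columns tolerated).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import AsvTable
from .imaging import ConversionTable

#: accepted aliases for required object-table columns
_OBJECT_ALIASES = {
    "object_id": ("object_id", "objid"),
    "station": ("station", "sample_id", "sample"),
    "fraction": ("fraction", "size_fraction"),
    "split": ("split", "split_factor", "acq_sub_part"),
    "object_major": ("object_major", "major"),
    "object_minor": ("object_minor", "minor"),
    "lineage": ("lineage", "taxon", "object_annotation_hierarchy"),
    "status": ("status", "object_annotation_status"),
}


def read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_tsv(path, index_col=0) -> pd.DataFrame:
    """Read a TSV skipping '#' metadata lines; metadata in ``df.attrs``."""
    meta = read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    df.attrs["meta"] = meta
    return df


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=index, float_format="%.10g")
    path.write_text(buf.getvalue())


def read_objects(path) -> pd.DataFrame:
    """Read an imaging object table, mapping known column aliases onto the
    canonical names and dropping unrecognized extras."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for canonical, aliases in _OBJECT_ALIASES.items():
        found = next((a for a in aliases if a in df.columns), None)
        if found is None:
            raise ValueError(f"object table {path} lacks a column for {canonical!r} "
                             f"(accepted: {aliases})")
        rename[found] = canonical
    out = df.rename(columns=rename)
    out["lineage"] = out["lineage"].fillna("")
    return out


def read_asv_table(path, marker: str | None = None) -> AsvTable:
    """Read an ASV table (rows: asv_id + lineage; columns station|fraction)."""
    meta = read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "lineage" not in df.columns:
        raise ValueError(f"ASV table {path} lacks a 'lineage' column")
    lineages = df["lineage"].fillna("")
    counts = df.drop(columns=["lineage"]).astype(np.int64)
    try:
        cols = [tuple(c.split("|", 1)) for c in counts.columns]
    except Exception as exc:
        raise ValueError(f"ASV table columns must be 'station|fraction': {exc}") from exc
    if any(len(c) != 2 for c in cols):
        raise ValueError("ASV table columns must be 'station|fraction'")
    counts.columns = pd.MultiIndex.from_tuples(cols, names=["station", "fraction"])
    table = AsvTable(marker or meta.get("marker", "?"), counts, lineages)
    table.counts.attrs["meta"] = meta
    return table


def write_asv_table(table: AsvTable, path, meta: dict | None = None) -> None:
    flat = table.counts.copy()
    flat.columns = [f"{s}|{f}" for s, f in table.counts.columns]
    flat.insert(0, "lineage", table.lineages.loc[flat.index])
    flat.index.name = "asv_id"
    write_tsv(flat, path, {"marker": table.marker, **(meta or {})})


def read_conversion_table(path, default: float | None = None) -> ConversionTable:
    """Read a two-column (taxon, factor) TSV into a ConversionTable."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"taxon", "factor"}.issubset(df.columns):
        raise ValueError(f"conversion table {path} needs 'taxon' and 'factor' columns")
    return ConversionTable(
        factors=dict(zip(df["taxon"], df["factor"].astype(float))), default=default
    )


def write_matrix(matrix: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a community matrix with its units in the metadata header."""
    info = {"units": matrix.attrs.get("units", "")}
    info.update(meta or {})
    write_tsv(matrix, path, info)
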