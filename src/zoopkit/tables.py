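"""Shared tabular data structures.

``AsvTable`` holds one marker's ASV x (station, size fraction) read counts
together with per-ASV lineage strings.  Community matrices are plain
:class:`pandas.DataFrame` objects (stations x taxa) whose columns are
lineage strings and whose ``attrs['units']`` names the currency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AsvTable:
    """Read counts for one marker.

    Parameters
    ----------
    marker : str
        Marker label, e.g. ``"COI"``, ``"V4"`` or ``"V9"``.
    counts : pandas.DataFrame
        Integer reads, index = ASV ids, columns = MultiIndex
        ``(station, fraction)``.
    lineages : pandas.Series
        ASV id -> lineage string (see :mod:`zoopkit.taxonomy`).
    """

    marker: str
    counts: pd.DataFrame
    lineages: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts columns must be a (station, fraction) MultiIndex")
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.issubdtype(vals.dtype, np.number)):
            raise ValueError("read counts must be non-negative numbers")
        missing = self.counts.index.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"{len(missing)} ASVs lack a lineage entry")
        self.lineages = self.lineages.loc[self.counts.index]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def stations(self) -> list:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    def subset(self, asv_ids) -> "AsvTable":
        return AsvTable(self.marker, self.counts.loc[asv_ids], self.lineages.loc[asv_ids])

    def copy(self) -> "AsvTable":
        return AsvTable(self.marker, self.counts.copy(), self.lineages.copy())


def make_asv_table(marker: str, counts: dict, lineages: dict) -> AsvTable:
    """Convenience constructor from plain dicts.

    ``counts`` maps ``(station, fraction)`` -> {asv_id: reads}.
    """
    df = pd.DataFrame(counts).fillna(0).astype(np.int64)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["station", "fraction"])
    return AsvTable(marker, df, pd.Series(lineages, name="lineage"))


def community_matrix(values: pd.DataFrame, units: str) -> pd.DataFrame:
    """Tag a stations x taxa frame with its currency/units label."""
    out = values.copy()
    out.attrs["units"] = units
    out.index.name = "station"
    return out
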