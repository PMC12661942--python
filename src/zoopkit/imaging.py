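"""Image-based quantification: biovolume, dry mass and community matrices.

Per-object ellipse axes (mm) are turned into individual biovolumes via the
prolate-spheroid formula, converted to dry mass with taxon-specific
wet-to-dry conversion factors (neutral buoyancy, density 1 g/cm3, so
1 mm3 wet mass = 1 mg), corrected for Motoda split factors, summed per
taxon and station, and divided by the filtered water volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import community_matrix
from .taxonomy import RANKS, parse_lineage

KNOT_MS = 0.514444  # metres per second in one knot

#: column names expected in an object table (extra columns are ignored)
OBJECT_COLUMNS = (
    "object_id",
    "station",
    "fraction",
    "split",
    "object_major",
    "object_minor",
    "lineage",
    "status",
)

CURRENCIES = ("abundance", "biovolume", "biomass")
_UNITS = {
    "abundance": "ind/m3",
    "biovolume": "mm3/m3",
    "biomass": "mg DM/m3",
}


def pixels_to_mm(length_px: float, dpi: float) -> float:
    """Convert a pixel length at *dpi* resolution to millimetres."""
    if dpi <= 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return length_px * 25.4 / dpi


def ellipsoid_biovolume(major, minor):
    """Prolate-spheroid biovolume (mm3): (4/3)*pi*(major/2)*(minor/2)**2.

    *major* is the polar axis.  Accepts scalars or arrays; the axes must
    satisfy ``major >= minor > 0`` elementwise.
    """
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    if np.any(minor <= 0):
        raise ValueError("minor axis must be positive")
    if np.any(minor > major):
        raise ValueError("minor axis exceeds major axis (axes swapped upstream?)")
    bv = (4.0 / 3.0) * math.pi * (major / 2.0) * (minor / 2.0) ** 2
    return float(bv) if bv.ndim == 0 else bv


@dataclass
class ConversionTable:
    """Wet-to-dry conversion factor lookup with rank-by-rank fallback.

    ``factors`` maps a taxon name at any rank to a factor in (0, 1].
    Lookup tries the most-resolved name of a lineage first, then walks up
    toward phylum; if nothing matches, ``default`` is used, and if that is
    ``None`` either an error is raised or (``on_missing='default1'``)
    a factor of 1 is returned.
    """

    factors: dict = field(default_factory=dict)
    default: float | None = None
    density_g_cm3: float = 1.0
    on_missing: str = "error"  # 'error' or 'default1'

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if not (0 < f <= 1):
                raise ValueError(f"conversion factor for {name!r} must be in (0,1], got {f}")
        if self.default is not None and not (0 < self.default <= 1):
            raise ValueError("default conversion factor must be in (0,1]")

    def lookup(self, lineage) -> float:
        if isinstance(lineage, str):
            lineage = parse_lineage(lineage)
        for rank in reversed(RANKS):
            name = lineage.get(rank, "")
            if name and name in self.factors:
                return self.factors[name]
        if self.default is not None:
            return self.default
        if self.on_missing == "default1":
            return 1.0
        raise KeyError(f"no conversion factor resolvable for lineage {lineage}")


#: factors shipped with the package: Arctic copepods 0.16, with the
#: large Calanus hyperboreus reduced to 0.08; other groups user-supplied.
DEFAULT_CONVERSIONS = ConversionTable(
    factors={"Copepoda": 0.16, "Calanus hyperboreus": 0.08},
    default=None,
)


def object_dry_mass(bv, lineage, cf_table: ConversionTable):
    """Individual dry mass (mg) from biovolume (mm3) and a lineage.

    With density 1 g/cm3 the biovolume numerically equals wet mass in mg,
    so DM = BV * density * cf.
    """
    bv = np.asarray(bv, dtype=float)
    if np.any(bv < 0):
        raise ValueError("biovolume must be non-negative")
    cf = cf_table.lookup(lineage)
    dm = bv * cf_table.density_g_cm3 * cf
    return float(dm) if dm.ndim == 0 else dm


def filtered_volume(net_area_m2: float, speed_knots: float, duration_s: float) -> float:
    """Filtered water volume (m3) = net area x ship speed x tow duration."""
    if net_area_m2 <= 0 or speed_knots <= 0 or duration_s <= 0:
        raise ValueError("net area, speed and duration must all be positive")
    return net_area_m2 * speed_knots * KNOT_MS * duration_s


def apply_length_species_lookup(objects: pd.DataFrame, rules) -> pd.DataFrame:
    """Optional length->species reassignment (e.g. Calanus prosome length).

    ``rules`` is a list of ``(genus, lo_mm, hi_mm, species_lineage_string)``;
    objects of that genus with major axis in [lo, hi) get the new lineage.
    No default cutoffs ship with the package.
    """
    out = objects.copy()
    for genus, lo, hi, new_lineage in rules:
        genus_of = out["lineage"].map(lambda s: parse_lineage(s)["genus"])
        mask = (genus_of == genus) & (out["object_major"] >= lo) & (out["object_major"] < hi)
        out.loc[mask, "lineage"] = new_lineage
    return out


def _validate_objects(objects: pd.DataFrame) -> None:
    missing = [c for c in OBJECT_COLUMNS if c not in objects.columns]
    if missing:
        raise ValueError(f"object table lacks required columns: {missing}")


def accounting_report(objects: pd.DataFrame) -> dict:
    """Uploaded / discarded / retained object counts by status flag."""
    _validate_objects(objects)
    uploaded = len(objects)
    retained = int((objects["status"] == "validated").sum())
    return {
        "uploaded": uploaded,
        "discarded": uploaded - retained,
        "retained": retained,
    }


def station_matrix(
    objects: pd.DataFrame,
    meta: pd.DataFrame,
    currency: str,
    cf_table: ConversionTable | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build a station x taxon community matrix in one currency.

    Each validated object contributes ``value / split_factor`` to its
    station x lineage cell (value = 1, biovolume, or dry mass), and every
    station row is divided by that station's filtered volume (from
    ``meta``, indexed by station with a ``filtered_volume`` column).

    Returns the matrix and an accounting dict
    (uploaded / discarded / retained).
    """
    if currency not in CURRENCIES:
        raise ValueError(f"currency must be one of {CURRENCIES}, got {currency!r}")
    _validate_objects(objects)
    if cf_table is None:
        cf_table = DEFAULT_CONVERSIONS

    report = accounting_report(objects)
    obj = objects[objects["status"] == "validated"].copy()

    if (obj["split"] <= 0).any() or (obj["split"] > 1).any():
        raise ValueError("split factors must lie in (0, 1]")
    stations = obj["station"].unique()
    missing_vol = [s for s in stations if s not in meta.index]
    if missing_vol:
        raise ValueError(f"missing filtered volume for stations: {missing_vol}")
    vol = meta["filtered_volume"].astype(float)
    if (vol.loc[stations] <= 0).any():
        raise ValueError("filtered volumes must be positive")

    if currency == "abundance":
        value = np.ones(len(obj))
    else:
        bv = ellipsoid_biovolume(obj["object_major"].to_numpy(), obj["object_minor"].to_numpy())
        if currency == "biovolume":
            value = bv
        else:
            cfs = obj["lineage"].map(cf_table.lookup).to_numpy(dtype=float)
            value = bv * cf_table.density_g_cm3 * cfs

    obj = obj.assign(_value=value / obj["split"].to_numpy(dtype=float))
    wide = obj.pivot_table(
        index="station", columns="lineage", values="_value", aggfunc="sum", fill_value=0.0
    )
    wide = wide.div(vol.loc[wide.index], axis=0)
    wide.columns.name = "taxon"
    return community_matrix(wide, _UNITS[currency]), report


def station_totals(matrix: pd.DataFrame) -> pd.Series:
    """Per-station totals (row sums), same units as the matrix."""
    totals = matrix.sum(axis=1)
    totals.name = "total"
    return totals
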