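"""Forward simulation of the zooplankton observation chain.

community densities -> net tow (Poisson catch) -> individual body sizes
-> sieve fractionation and Motoda splitting (imaging stream) -> biomass-
proportional, bias-weighted marker reads (sequencing stream).

Every stochastic step is driven by :class:`numpy.random.Generator`
instances derived from a single scenario seed, so the whole dataset is
bit-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging
from .tables import AsvTable
from .taxonomy import RANKS, format_lineage, truncate_lineage

MARKERS = ("COI", "V4", "V9")

ENV_COLUMNS = (
    "latitude",
    "mean_temperature",
    "mean_salinity",
    "mean_fluorescence",
    "mean_ice_thickness",
    "pct_PSW",
)


class InvalidScenarioError(ValueError):
    """Raised when a simulation scenario violates its invariants."""


@dataclass(frozen=True)
class TaxonSpec:
    """Simulator-side properties of one taxon."""

    name: str
    lineage: dict
    mean_density0: float  # ind/m3 at the reference latitude
    latitude_slope: float  # log-density change per degree latitude
    temp_affinity: float  # signed coupling of log-density to mean temperature
    length_meanlog: float  # lognormal params of the major axis (mm)
    length_sdlog: float
    aspect_ratio: float  # major/minor, >= 1
    conversion_factor: float  # wet->dry mass, in (0, 1]
    amp_efficiency: dict  # marker -> relative amplification weight >= 0
    resolution: dict  # marker -> deepest reported rank
    imaging_resolution: str = "species"

    def __post_init__(self) -> None:
        if self.mean_density0 < 0:
            raise InvalidScenarioError(f"{self.name}: density must be >= 0")
        if self.aspect_ratio < 1:
            raise InvalidScenarioError(f"{self.name}: aspect_ratio must be >= 1")
        if not (0 < self.conversion_factor <= 1):
            raise InvalidScenarioError(f"{self.name}: conversion_factor must be in (0,1]")
        if not self.lineage.get("phylum"):
            raise InvalidScenarioError(f"{self.name}: lineage must carry a phylum")
        if any(v < 0 for v in self.amp_efficiency.values()):
            raise InvalidScenarioError(f"{self.name}: amp_efficiency must be >= 0")


@dataclass(frozen=True)
class StationSpec:
    station: str
    latitude: float
    longitude: float
    env: dict  # covariate name -> value


@dataclass
class ScenarioConfig:
    """Sampling-and-observation scenario; ``seed`` fixes all randomness."""

    stations: list
    net_area_m2: float = 1.0
    tow_speed_knots: float = 2.5
    tow_duration_s: float = 700.0
    sieve_cutoffs_mm: tuple = (0.5, 1.0, 2.0, 4.0)
    motoda_min_fraction: float = 1.0 / 256.0
    target_particles_per_aliquot: int = 1000
    seq_depth_range: tuple = (60_000, 120_000)
    seed: int = 0
    reference_latitude: float | None = None
    density_sigma: float = 0.25
    max_asvs_per_taxon: int = 3
    singletons_per_fraction: tuple = (0, 4)
    artifact_fraction: float = 0.5  # non-organism objects per organism retained

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.sieve_cutoffs_mm)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise InvalidScenarioError("sieve cutoffs must be strictly increasing")
        k = -math.log2(self.motoda_min_fraction)
        if abs(k - round(k)) > 1e-9 or self.motoda_min_fraction > 1:
            raise InvalidScenarioError("motoda_min_fraction must be 2**-k")
        if self.reference_latitude is None:
            self.reference_latitude = min(s.latitude for s in self.stations)

    @property
    def filtered_volume(self) -> float:
        return imaging.filtered_volume(self.net_area_m2, self.tow_speed_knots, self.tow_duration_s)

    def fraction_labels(self) -> list:
        cuts = list(self.sieve_cutoffs_mm)
        labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(cuts, cuts[1:])]
        labels.append(f">{cuts[-1]:g}")
        return labels


def default_stations(n_stations: int = 12, seed: int = 0) -> list:
    """A poleward transect with a strong temperature / PSW gradient."""
    rng = np.random.default_rng(seed)
    lats = np.linspace(80.5, 83.7, n_stations)
    out = []
    for i, lat in enumerate(lats):
        x = lat - 80.5
        env = {
            "latitude": round(float(lat), 4),
            "mean_temperature": round(float(2.4 - 1.1 * x + rng.normal(0, 0.15)), 3),
            "mean_salinity": round(float(34.8 - 0.18 * x + rng.normal(0, 0.03)), 3),
            "mean_fluorescence": round(float(np.clip(0.8 - 0.05 * x + rng.normal(0, 0.2), 0.05, None)), 3),
            "mean_ice_thickness": round(float(np.clip(0.1 + 0.45 * x + rng.normal(0, 0.1), 0.0, None)), 3),
            "pct_PSW": round(float(np.clip(8 + 27 * x + rng.normal(0, 4), 0, 100)), 2),
        }
        out.append(
            StationSpec(
                station=f"S{i + 1:02d}",
                latitude=env["latitude"],
                longitude=round(float(30.0 - 1.2 * i + rng.normal(0, 0.3)), 4),
                env=env,
            )
        )
    return out


def default_scenario(seed: int = 0, n_stations: int = 12, **overrides) -> ScenarioConfig:
    return ScenarioConfig(stations=default_stations(n_stations, seed), seed=seed, **overrides)


_PHYLA = (
    # (phylum, class, order, group latitude slope) templates the pool
    # draws from; group-level slopes make the poleward decline visible at
    # every aggregation rank (the Calanoida analogue persists north, the
    # warm-water groups collapse), as in the survey this emulates
    ("Arthropoda", "Copepoda", "Calanoida", -0.05),
    ("Arthropoda", "Malacostraca", "Amphipoda", -1.0),
    ("Arthropoda", "Malacostraca", "Euphausiacea", -1.4),
    ("Chaetognatha", "Sagittoidea", "Aphragmophora", -0.7),
    ("Cnidaria", "Hydrozoa", "Trachymedusae", -1.6),
    ("Mollusca", "Gastropoda", "Pteropoda", -1.8),
    ("Chordata", "Appendicularia", "Copelata", -1.2),
    ("Annelida", "Polychaeta", "Phyllodocida", -1.5),
)


def make_taxon_pool(n_taxa: int, seed: int, equal_efficiency: bool = False) -> list:
    """Deterministic pool of :class:`TaxonSpec`.

    Always includes (i) a large-bodied dominant taxon with the reduced
    conversion factor 0.08 (the *Calanus hyperboreus* analogue, which
    increases poleward) and (ii) one taxon invisible to the V4 marker.
    All other taxa decline poleward and prefer warmer water, producing a
    community whose abundance and diversity fall with latitude.

    With ``equal_efficiency=True`` all non-zero amplification weights are
    1, so reads are strictly biomass-proportional.
    """
    if n_taxa < 2:
        raise InvalidScenarioError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n_taxa):
        phylum, cls, order, group_slope = _PHYLA[int(rng.integers(len(_PHYLA)))]
        family = f"{order[:6]}idae{i % 5}"
        genus = f"Genus{i:02d}"
        species = f"{genus} sp{i:02d}"
        lineage = dict(
            zip(RANKS, (phylum, cls, order, family, genus, species))
        )
        amp = {
            m: (1.0 if equal_efficiency else float(rng.lognormal(0.0, 0.7)))
            for m in MARKERS
        }
        resolution = {
            "COI": "species",
            "V4": "family" if rng.random() < 0.6 else "order",
            "V9": "family" if rng.random() < 0.4 else "order",
        }
        spec = TaxonSpec(
            name=species,
            lineage=lineage,
            mean_density0=float(rng.lognormal(0.4, 0.6)),
            latitude_slope=float(group_slope - rng.uniform(0.0, 0.15)),
            temp_affinity=float(rng.uniform(0.05, 0.30)),
            length_meanlog=float(rng.normal(math.log(1.2), 0.2)),
            length_sdlog=float(rng.uniform(0.15, 0.35)),
            aspect_ratio=float(rng.uniform(2.0, 4.0)),
            conversion_factor=0.16 if phylum == "Arthropoda" else float(rng.uniform(0.05, 0.2)),
            amp_efficiency=amp,
            resolution=resolution,
            imaging_resolution="species" if rng.random() < 0.7 else "genus",
        )
        pool.append(spec)

    # taxon 0: the large-bodied, poleward-increasing dominant with cf 0.08
    big = pool[0]
    lineage = dict(zip(RANKS, ("Arthropoda", "Copepoda", "Calanoida", "Calanidae",
                               "Calanusoid", "Calanusoid giganteus")))
    pool[0] = TaxonSpec(
        name=lineage["species"],
        lineage=lineage,
        mean_density0=6.0,
        latitude_slope=0.05,
        temp_affinity=-0.05,
        length_meanlog=math.log(6.0),
        length_sdlog=0.18,
        aspect_ratio=3.0,
        conversion_factor=0.08,
        amp_efficiency=big.amp_efficiency,
        resolution={"COI": "species", "V4": "family", "V9": "order"},
        imaging_resolution="species",
    )
    # taxon 1: the V4 dropout (amphipod analogue)
    drop = pool[1]
    amp = dict(drop.amp_efficiency)
    amp["V4"] = 0.0
    lineage = dict(zip(RANKS, ("Arthropoda", "Malacostraca", "Amphipoda",
                               "Hyperiidae", "Themistoid", "Themistoid libellulae")))
    pool[1] = TaxonSpec(
        name=lineage["species"],
        lineage=lineage,
        mean_density0=drop.mean_density0,
        latitude_slope=drop.latitude_slope,
        temp_affinity=drop.temp_affinity,
        length_meanlog=math.log(3.0),
        length_sdlog=0.25,
        aspect_ratio=2.5,
        conversion_factor=0.16,
        amp_efficiency=amp,
        resolution={"COI": "species", "V4": "family", "V9": "order"},
        imaging_resolution="species",
    )
    return pool


def expected_density(pool: list, scenario: ScenarioConfig) -> pd.DataFrame:
    """Noise-free expected density (ind/m3), stations x taxa."""
    lat0 = scenario.reference_latitude
    rows = {}
    for st in scenario.stations:
        temp = st.env["mean_temperature"]
        rows[st.station] = {
            t.name: t.mean_density0
            * math.exp(t.latitude_slope * (st.latitude - lat0) + t.temp_affinity * temp)
            for t in pool
        }
    df = pd.DataFrame(rows).T.loc[[s.station for s in scenario.stations], [t.name for t in pool]]
    df.index.name = "station"
    return df


def simulate_community(pool: list, scenario: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Realized true density matrix: lognormal variation around expectation
    (mean-preserving: E[realized] = expected)."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    mu = expected_density(pool, scenario)
    sigma = scenario.density_sigma
    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=mu.shape)
    return mu * noise


def simulate_tow(density: pd.Series, filtered_volume: float, rng) -> pd.Series:
    """Poisson catch counts per taxon for one station."""
    if filtered_volume < 0:
        raise ValueError("filtered volume must be non-negative")
    lam = density.to_numpy(dtype=float) * filtered_volume
    counts = pd.Series(rng.poisson(lam), index=density.index, name="count")
    return counts


def simulate_individuals(catch: pd.Series, pool: list, rng) -> pd.DataFrame:
    """Body sizes for every caught individual.

    Columns: taxon, object_major, object_minor, lineage (truncated to the
    per-taxon imaging resolution).  The untruncated taxon name is kept for
    truth bookkeeping.
    """
    by_name = {t.name: t for t in pool}
    frames = []
    for name, n in catch.items():
        n = int(n)
        if n == 0:
            continue
        spec = by_name[name]
        major = rng.lognormal(spec.length_meanlog, spec.length_sdlog, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "taxon": name,
                    "object_major": major,
                    "object_minor": major / spec.aspect_ratio,
                    "lineage": format_lineage(
                        truncate_lineage(spec.lineage, spec.imaging_resolution)
                    ),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["taxon", "object_major", "object_minor", "lineage"])
    return pd.concat(frames, ignore_index=True)


def motoda_split_factor(n: int, target: int, min_fraction: float) -> float:
    """Halve until the expected retained count is <= target (clamped)."""
    f = 1.0
    while n * f > target and f > min_fraction:
        f /= 2.0
    return max(f, min_fraction)


def assign_fractions(major: np.ndarray, cutoffs) -> np.ndarray:
    """Half-open sieve intervals [lo, hi) on the major axis; values below
    the smallest cutoff get the below-mesh label."""
    cuts = np.asarray(cutoffs, dtype=float)
    labels = np.array([f"<{cuts[0]:g}"]
                      + [f"{lo:g}-{hi:g}" for lo, hi in zip(cuts, cuts[1:])]
                      + [f">{cuts[-1]:g}"])
    idx = np.searchsorted(cuts, np.asarray(major, dtype=float), side="right")
    return labels[idx]


def sieve_and_split(objects: pd.DataFrame, scenario: ScenarioConfig, rng):
    """Sieve objects into size fractions, Motoda-split each fraction and
    retain objects Bernoulli(split factor).

    Returns ``(retained, splits)``: the retained objects with ``fraction``
    and ``split`` columns (below-mesh objects excluded), and the split
    factor per fraction label.
    """
    obj = objects.copy()
    obj["fraction"] = assign_fractions(obj["object_major"].to_numpy(), scenario.sieve_cutoffs_mm)
    below = f"<{scenario.sieve_cutoffs_mm[0]:g}"
    obj = obj[obj["fraction"] != below]

    splits = {}
    kept = []
    for frac in scenario.fraction_labels():
        sub = obj[obj["fraction"] == frac]
        f = motoda_split_factor(
            len(sub), scenario.target_particles_per_aliquot, scenario.motoda_min_fraction
        )
        splits[frac] = f
        if len(sub):
            retain = rng.random(len(sub)) < f
            sub = sub[retain].copy()
            sub["split"] = f
            kept.append(sub)
    if kept:
        retained = pd.concat(kept, ignore_index=True)
    else:
        retained = obj.iloc[0:0].copy()
        retained["split"] = pd.Series(dtype=float)
    return retained, splits


def biomass_by_fraction(objects: pd.DataFrame, pool: list) -> pd.DataFrame:
    """True dry mass (mg) per fraction x taxon from individual sizes."""
    cf = {t.name: t.conversion_factor for t in pool}
    bv = imaging.ellipsoid_biovolume(
        objects["object_major"].to_numpy(), objects["object_minor"].to_numpy()
    )
    dm = bv * objects["taxon"].map(cf).to_numpy(dtype=float)
    out = (
        objects.assign(_dm=dm)
        .pivot_table(index="fraction", columns="taxon", values="_dm", aggfunc="sum", fill_value=0.0)
    )
    return out


def simulate_reads(
    biomass: pd.DataFrame,
    pool: list,
    marker: str,
    scenario: ScenarioConfig,
    rng,
    station: str,
    depth=None,
) -> AsvTable:
    """Marker reads for one station's size fractions.

    Per fraction, reads ~ Multinomial(depth, p) with p proportional to
    taxon dry mass x amplification efficiency.  Each taxon's reads are
    spread over 1..max_asvs_per_taxon ASVs (weights fixed per taxon within
    the call), lineages are truncated to the marker's resolution for that
    taxon, and a few brand-new singleton ASVs (1 read each) are injected
    as noise.  The injected count is recorded in
    ``counts.attrs['injected_singletons']``.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    by_name = {t.name: t for t in pool}
    taxa = [t for t in biomass.columns if t in by_name]

    n_asv = {}
    asv_weights = {}
    for t in taxa:
        m = int(rng.integers(1, scenario.max_asvs_per_taxon + 1))
        n_asv[t] = m
        w = rng.dirichlet(np.ones(m) * 5.0) if m > 1 else np.ones(1)
        asv_weights[t] = w

    if depth is None:
        depth_range = scenario.seq_depth_range
    cols = {}
    lineages = {}
    injected = 0
    singleton_id = 0
    for frac in biomass.index:
        if depth is None:
            d = int(rng.integers(depth_range[0], depth_range[1] + 1))
        else:
            d = int(depth)
        if d <= 0:
            raise ValueError("sequencing depth must be positive")
        weight = np.array(
            [biomass.loc[frac, t] * by_name[t].amp_efficiency[marker] for t in taxa]
        )
        col: dict = {}
        if weight.sum() > 0:
            p = weight / weight.sum()
            taxon_reads = rng.multinomial(d, p)
            for t, r in zip(taxa, taxon_reads):
                if r == 0:
                    continue
                per_asv = rng.multinomial(r, asv_weights[t]) if n_asv[t] > 1 else np.array([r])
                spec = by_name[t]
                lin = format_lineage(
                    truncate_lineage(spec.lineage, spec.resolution[marker])
                )
                for j, rj in enumerate(per_asv):
                    if rj == 0:
                        continue
                    asv_id = f"{marker}_{taxa.index(t):03d}_{j}"
                    col[asv_id] = col.get(asv_id, 0) + int(rj)
                    lineages[asv_id] = lin
        lo, hi = scenario.singletons_per_fraction
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            host = by_name[taxa[int(rng.integers(len(taxa)))]]
            asv_id = f"{marker}_sing_{station}_{singleton_id}"
            singleton_id += 1
            col[asv_id] = 1
            lineages[asv_id] = format_lineage(
                truncate_lineage(host.lineage, host.resolution[marker])
            )
            injected += 1
        cols[(station, frac)] = col

    counts = pd.DataFrame(cols).fillna(0).astype(np.int64)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["station", "fraction"])
    counts.attrs["injected_singletons"] = injected
    return AsvTable(marker, counts, pd.Series(lineages, name="lineage"))


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict, index=True) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def generate_dataset(
    scenario: ScenarioConfig, outdir, pool: list | None = None, n_taxa: int = 20,
    equal_efficiency: bool = False,
) -> dict:
    """Simulate everything and write the dataset directory.

    Files written (all tab-separated, '#'-prefixed metadata headers):
    ``objects.tsv``, ``asv_<marker>.tsv`` (x3), ``env.tsv``,
    ``stations.tsv``, ``conversion_factors.tsv``, truth tables
    (``truth_density.tsv``, ``truth_biomass.tsv``,
    ``truth_read_weights_<marker>.tsv``) and ``scenario.yaml``.
    Re-running with the same scenario produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pool is None:
        pool = make_taxon_pool(n_taxa, scenario.seed, equal_efficiency=equal_efficiency)
    rng = np.random.default_rng(scenario.seed)
    volume = scenario.filtered_volume

    density = simulate_community(pool, scenario, rng)
    all_objects = []
    truth_biomass = {}
    marker_tables: dict = {m: [] for m in MARKERS}
    read_weights = {m: {} for m in MARKERS}
    next_id = 1
    for st in scenario.stations:
        catch = simulate_tow(density.loc[st.station], volume, rng)
        individuals = simulate_individuals(catch, pool, rng)
        bm = biomass_by_fraction(
            individuals.assign(
                fraction=assign_fractions(
                    individuals["object_major"].to_numpy(), scenario.sieve_cutoffs_mm
                )
            ).query(f"fraction != '<{scenario.sieve_cutoffs_mm[0]:g}'"),
            pool,
        ).reindex(scenario.fraction_labels(), fill_value=0.0)
        truth_biomass[st.station] = bm.sum(axis=0)

        retained, _splits = sieve_and_split(individuals, scenario, rng)
        retained = retained.assign(station=st.station, status="validated")
        n_art = int(round(len(retained) * scenario.artifact_fraction))
        if n_art:
            art = pd.DataFrame(
                {
                    "taxon": "",
                    "object_major": rng.lognormal(0.2, 0.5, n_art),
                    "object_minor": 0.0,
                    "lineage": "",
                    "fraction": rng.choice(scenario.fraction_labels(), n_art),
                    "split": 1.0,
                    "station": st.station,
                    "status": rng.choice(["detritus", "artifact", "body-part"], n_art),
                }
            )
            art["object_minor"] = art["object_major"] * 0.5
            retained = pd.concat([retained, art], ignore_index=True)
        retained.insert(0, "object_id", [f"obj{next_id + i:07d}" for i in range(len(retained))])
        next_id += len(retained)
        all_objects.append(retained)

        by_name = {t.name: t for t in pool}
        for marker in MARKERS:
            tab = simulate_reads(bm, pool, marker, scenario, rng, station=st.station)
            marker_tables[marker].append(tab)
            w = {
                t: float(truth_biomass[st.station].get(t, 0.0))
                * by_name[t].amp_efficiency[marker]
                for t in density.columns
            }
            tot = sum(w.values())
            read_weights[marker][st.station] = {
                t: (v / tot if tot > 0 else 0.0) for t, v in w.items()
            }

    meta = {"seed": scenario.seed, "generator": "zoopkit.synthetic"}

    objects = pd.concat(all_objects, ignore_index=True)
    objects = objects[
        ["object_id", "station", "fraction", "split", "object_major", "object_minor",
         "lineage", "status", "taxon"]
    ]
    _write_tsv(objects, outdir / "objects.tsv", meta, index=False)

    for marker in MARKERS:
        tabs = marker_tables[marker]
        counts = pd.concat([t.counts for t in tabs], axis=1).fillna(0).astype(np.int64)
        lineages = pd.concat([t.lineages for t in tabs])
        lineages = lineages[~lineages.index.duplicated()]
        flat = counts.copy()
        flat.columns = [f"{s}|{f}" for s, f in counts.columns]
        flat.insert(0, "lineage", lineages.loc[flat.index])
        flat.index.name = "asv_id"
        flat = flat.sort_index()
        injected = sum(t.counts.attrs.get("injected_singletons", 0) for t in tabs)
        _write_tsv(flat, outdir / f"asv_{marker}.tsv", {**meta, "marker": marker,
                                                        "injected_singletons": injected})

    env = pd.DataFrame({st.station: st.env for st in scenario.stations}).T
    env = env[list(ENV_COLUMNS)]
    env.index.name = "station"
    _write_tsv(env, outdir / "env.tsv", meta)

    stations = pd.DataFrame(
        {
            st.station: {
                "latitude": st.latitude,
                "longitude": st.longitude,
                "net_area_m2": scenario.net_area_m2,
                "tow_speed_knots": scenario.tow_speed_knots,
                "tow_duration_s": scenario.tow_duration_s,
                "filtered_volume": volume,
            }
            for st in scenario.stations
        }
    ).T
    stations.index.name = "station"
    _write_tsv(stations, outdir / "stations.tsv", meta)

    cf = pd.DataFrame(
        [
            {"taxon": t.lineage["species"], "factor": t.conversion_factor}
            for t in pool
        ]
    )
    _write_tsv(cf, outdir / "conversion_factors.tsv", meta, index=False)

    density.index.name = "station"
    _write_tsv(density, outdir / "truth_density.tsv", meta)
    tb = pd.DataFrame(truth_biomass).T
    tb.index.name = "station"
    _write_tsv(tb / volume, outdir / "truth_biomass.tsv", {**meta, "units": "mg DM/m3"})
    for marker in MARKERS:
        w = pd.DataFrame(read_weights[marker]).T
        w.index.name = "station"
        _write_tsv(w, outdir / f"truth_read_weights_{marker}.tsv", {**meta, "marker": marker})

    lin_map = pd.DataFrame(
        [{"taxon": t.name, "lineage": format_lineage(t.lineage)} for t in pool]
    )
    _write_tsv(lin_map, outdir / "truth_lineages.tsv", meta, index=False)

    cfg = {
        "seed": scenario.seed,
        "n_stations": len(scenario.stations),
        "n_taxa": len(pool),
        "net_area_m2": scenario.net_area_m2,
        "tow_speed_knots": scenario.tow_speed_knots,
        "tow_duration_s": scenario.tow_duration_s,
        "sieve_cutoffs_mm": list(scenario.sieve_cutoffs_mm),
        "motoda_min_fraction": scenario.motoda_min_fraction,
        "target_particles_per_aliquot": scenario.target_particles_per_aliquot,
        "seq_depth_range": list(scenario.seq_depth_range),
        "equal_efficiency": equal_efficiency,
    }
    (outdir / "scenario.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    return {
        "outdir": str(outdir),
        "seed": scenario.seed,
        "stations": [st.station for st in scenario.stations],
        "markers": list(MARKERS),
        "fractions": scenario.fraction_labels(),
        "n_taxa": len(pool),
        "files": sorted(p.name for p in outdir.iterdir()),
    }
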