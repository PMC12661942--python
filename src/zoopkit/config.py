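"""Run configuration: one structured YAML file with fail-fast validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Paths and settings tying the pipeline stages together.

    Unknown keys in the YAML are rejected; ``seed`` is mandatory because
    every stochastic step derives its generator from it.
    """

    seed: int
    outdir: str = "results"
    dataset_dir: str | None = None  # where `simulate` writes / others read
    objects: str | None = None
    asv_tables: dict = field(default_factory=dict)  # marker -> path
    env_table: str | None = None
    station_meta: str | None = None
    conversion_factors: str | None = None
    metazoan_phyla: list | None = None
    ranks: list = field(default_factory=lambda: ["species"])
    n_stations: int = 12
    n_taxa: int = 20
    equal_efficiency: bool = False
    nmds_k: int = 2
    n_starts: int = 8
    n_perm: int = 999
    tol: float = 1e-9
    max_iter: int = 300
    n_clusters: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set 'seed'")
        return cls(**raw)

    def resolve_inputs(self) -> None:
        """Fill input paths from ``dataset_dir`` conventions when unset."""
        if self.dataset_dir is None:
            return
        d = Path(self.dataset_dir)
        self.objects = self.objects or str(d / "objects.tsv")
        if not self.asv_tables:
            self.asv_tables = {m: str(d / f"asv_{m}.tsv") for m in ("COI", "V4", "V9")}
        self.env_table = self.env_table or str(d / "env.tsv")
        self.station_meta = self.station_meta or str(d / "stations.tsv")
        self.conversion_factors = self.conversion_factors or str(d / "conversion_factors.tsv")

    def validate_paths(self, need=("objects", "asv_tables", "env_table", "station_meta")) -> None:
        missing = []
        for name in need:
            val = getattr(self, name)
            if val is None or (name == "asv_tables" and not val):
                missing.append(name)
                continue
            paths = val.values() if isinstance(val, dict) else [val]
            missing += [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing inputs: {missing}")
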