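# zoopkit

Integrative zooplankton community analysis in Python: image-based
quantification (abundance, biovolume, biomass), multi-marker metabarcoding
normalization (NSRA), cross-method taxonomic harmonization, and the full
diversity / ordination / environment-driver statistics battery — together
with a forward simulator of the whole observation chain so the pipeline can
be exercised end to end at desk scale without external data.

## What it does

- **`zoopkit.synthetic`** — simulates a poleward station transect: true
  taxon densities with latitude/temperature gradients, Poisson net-tow
  catches scaled by filtered volume, lognormal body sizes, sieve
  fractionation (0.5 / 1 / 2 / 4 mm), binary Motoda splitting to ≥ 1/256,
  biomass-proportional marker reads with per-taxon amplification bias and
  marker-specific taxonomic resolution, and singleton noise. Everything is
  bit-reproducible under one seed, and truth tables are written for
  parameter-recovery tests.
- **`zoopkit.imaging`** — per-object ellipsoid biovolume
  `(4/3)·π·(major/2)·(minor/2)²`, wet→dry conversion factors with
  rank-fallback lookup (copepods 0.16, *Calanus hyperboreus* 0.08),
  split-factor correction and division by filtered volume into
  station × taxon matrices in three currencies, with upload/discard
  accounting.
- **`zoopkit.metabarcoding`** — singleton removal, metazoan-phylum
  filtering with accounting reports, NSRA scaling of size fractions to the
  per-station minimum depth and merging, rank aggregation, and ASV
  accumulation curves.
- **`zoopkit.integration`** — cross-method taxon harmonization (rank-aware:
  a family-level record never merges into a species-level one), 4-set Venn
  counts, per-rank richness tables, dominant taxa.
- **`zoopkit.stats`** — square-root transform, Shannon, Jaccard,
  Bray–Curtis, matrix correlations with t-test (or optional Mantel)
  significance, PCA with passive vectors, a from-scratch non-metric MDS
  (isotonic regression + Guttman majorization, multi-start), permutational
  environmental vector fitting, and Ward/k-means station clustering.

## CLI

```sh
# simulate a dataset, then run the full analysis on it
zoopkit simulate --seed 1 --dataset-dir out/dataset
zoopkit imaging --seed 1 --dataset-dir out/dataset --outdir out
zoopkit metabarcode --seed 1 --dataset-dir out/dataset --outdir out
zoopkit analyze --seed 1 --dataset-dir out/dataset --outdir out
# or everything at once
zoopkit all --seed 1 --outdir out
```

All tabular I/O is TSV with `#`-prefixed metadata headers (tool version,
command, seed). A YAML run configuration can replace the flags
(`--config run.yaml`); unknown keys are rejected.

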