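import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from zoopkit import synthetic
from zoopkit.synthetic import (
    InvalidScenarioError,
    ScenarioConfig,
    assign_fractions,
    biomass_by_fraction,
    default_scenario,
    default_stations,
    expected_density,
    generate_dataset,
    make_taxon_pool,
    motoda_split_factor,
    sieve_and_split,
    simulate_community,
    simulate_individuals,
    simulate_reads,
    simulate_tow,
)


class TestTaxonPool:
    def test_determinism(self):
        a = make_taxon_pool(2, seed=1)
        b = make_taxon_pool(2, seed=1)
        assert len(a) == 2
        assert a == b

    def test_min_taxa(self):
        with pytest.raises(InvalidScenarioError):
            make_taxon_pool(1, seed=0)

    def test_v4_dropout_present(self):
        pool = make_taxon_pool(20, seed=7)
        assert any(t.amp_efficiency["V4"] == 0 for t in pool)

    def test_all_have_phylum(self):
        pool = make_taxon_pool(20, seed=7)
        assert all(t.lineage["phylum"] for t in pool)

    def test_large_bodied_distinct_cf(self):
        pool = make_taxon_pool(20, seed=3)
        big = max(pool, key=lambda t: t.length_meanlog)
        assert big.conversion_factor == 0.08
        assert math.exp(big.length_meanlog) > 4

    def test_equal_efficiency_flag(self):
        pool = make_taxon_pool(10, seed=5, equal_efficiency=True)
        effs = {e for t in pool for e in t.amp_efficiency.values()}
        assert effs <= {0.0, 1.0}


class TestScenario:
    def test_cutoffs_must_increase(self):
        with pytest.raises(InvalidScenarioError):
            ScenarioConfig(stations=default_stations(3), sieve_cutoffs_mm=(1, 1, 2, 4))

    def test_motoda_power_of_two(self):
        with pytest.raises(InvalidScenarioError):
            ScenarioConfig(stations=default_stations(3), motoda_min_fraction=0.3)

    def test_fraction_labels(self, small_scenario):
        assert small_scenario.fraction_labels() == ["0.5-1", "1-2", "2-4", ">4"]


class TestCommunity:
    def test_flat_gradient(self, small_pool, small_scenario):
        flat = [
            t.__class__(**{**t.__dict__, "latitude_slope": 0.0, "temp_affinity": 0.0})
            for t in small_pool
        ]
        mu = expected_density(flat, small_scenario)
        for col in mu.columns:
            assert mu[col].nunique() == 1

    def test_negative_slopes_monotone(self, small_scenario):
        pool = make_taxon_pool(6, seed=0)
        neg = [
            t.__class__(**{**t.__dict__, "latitude_slope": -0.4, "temp_affinity": 0.0})
            for t in pool
        ]
        totals = expected_density(neg, small_scenario).sum(axis=1)
        lats = [s.latitude for s in small_scenario.stations]
        assert all(
            b < a for a, b in zip(totals, totals[1:])
        ), f"not decreasing along {lats}"

    def test_determinism(self, small_pool, small_scenario):
        a = simulate_community(small_pool, small_scenario)
        b = simulate_community(small_pool, small_scenario)
        pd.testing.assert_frame_equal(a, b)


class TestTow:
    def test_zero_density(self, rng):
        counts = simulate_tow(pd.Series({"a": 0.0, "b": 0.0}), 500.0, rng)
        assert (counts == 0).all()

    def test_negative_volume(self, rng):
        with pytest.raises(ValueError):
            simulate_tow(pd.Series({"a": 1.0}), -5.0, rng)

    def test_poisson_mean_monte_carlo(self):
        # density=1, V=100: mean over many replicates within 3 s.e. of 100
        n_rep = 10_000
        rng = np.random.default_rng(0)
        draws = np.array(
            [simulate_tow(pd.Series({"a": 1.0}), 100.0, rng)["a"] for _ in range(n_rep)]
        )
        se = math.sqrt(100.0 / n_rep)
        assert abs(draws.mean() - 100.0) < 3 * se

    def test_volume_linearity_of_mean(self):
        rng = np.random.default_rng(1)
        d = pd.Series({"a": 2.0})
        m1 = np.mean([simulate_tow(d, 50.0, rng)["a"] for _ in range(4000)])
        m2 = np.mean([simulate_tow(d, 100.0, rng)["a"] for _ in range(4000)])
        assert m2 / m1 == pytest.approx(2.0, rel=0.05)


class TestIndividuals:
    def _one_taxon_pool(self, **kw):
        t = make_taxon_pool(2, seed=0)[0]
        return [t.__class__(**{**t.__dict__, **kw})]

    def test_aspect_ratio_one(self, rng):
        pool = self._one_taxon_pool(aspect_ratio=1.0)
        obj = simulate_individuals(pd.Series({pool[0].name: 50}), pool, rng)
        np.testing.assert_allclose(obj["object_major"], obj["object_minor"])

    def test_sdlog_zero(self, rng):
        pool = self._one_taxon_pool(length_sdlog=0.0, length_meanlog=math.log(2.5))
        obj = simulate_individuals(pd.Series({pool[0].name: 20}), pool, rng)
        np.testing.assert_allclose(obj["object_major"], 2.5)

    def test_lognormal_median(self, rng):
        pool = self._one_taxon_pool(length_meanlog=0.0, length_sdlog=0.3)
        obj = simulate_individuals(pd.Series({pool[0].name: 10_000}), pool, rng)
        assert np.median(obj["object_major"]) == pytest.approx(1.0, rel=0.01)

    def test_lineage_truncated_to_imaging_resolution(self, rng):
        pool = self._one_taxon_pool(imaging_resolution="family")
        obj = simulate_individuals(pd.Series({pool[0].name: 3}), pool, rng)
        assert all(";g__;s__" in lin for lin in obj["lineage"])


class TestSieveSplit:
    def test_assign_fractions_half_open(self):
        labels = assign_fractions(np.array([0.4, 0.5, 0.99, 1.0, 3.9, 4.0, 10.0]), (0.5, 1, 2, 4))
        assert list(labels) == ["<0.5", "0.5-1", "0.5-1", "1-2", "2-4", ">4", ">4"]

    def test_no_split_when_small(self):
        assert motoda_split_factor(100, 1000, 1 / 256) == 1.0

    def test_clamped_at_min_fraction(self):
        # 1e6 objects would need 1/1024; clamped to the 1/256 floor
        assert motoda_split_factor(1_000_000, 1000, 1 / 256) == 1 / 256

    def test_below_mesh_excluded(self, small_scenario, rng):
        obj = pd.DataFrame(
            {"taxon": "x", "object_major": [0.1, 0.2, 0.7], "object_minor": 0.05, "lineage": "p__A"}
        )
        retained, _ = sieve_and_split(obj, small_scenario, rng)
        assert (retained["object_major"] >= 0.5).all()

    def test_binomial_retention_mean(self, small_scenario):
        # expected retained = n * f, checked at 3 s.e. over 1000 replicates
        n = 4096
        f = motoda_split_factor(n, small_scenario.target_particles_per_aliquot, 1 / 256)
        assert f == 1 / 8
        rng = np.random.default_rng(0)
        kept = (rng.random((1000, n)) < f).sum(axis=1)
        se = math.sqrt(n * f * (1 - f) / 1000)
        assert abs(kept.mean() - n * f) < 3 * se

    def test_split_factor_recorded_per_fraction(self, small_scenario, rng):
        obj = pd.DataFrame(
            {
                "taxon": "x",
                "object_major": np.full(3000, 0.7),
                "object_minor": 0.3,
                "lineage": "p__A",
            }
        )
        retained, splits = sieve_and_split(obj, small_scenario, rng)
        assert splits["0.5-1"] == 0.25  # 3000 -> 1500 -> 750 <= 1000
        assert set(retained["split"]) == {0.25}


class TestReads:
    def _biomass(self):
        return pd.DataFrame(
            {"Calanusoid giganteus": [3.0, 1.0], "Themistoid libellulae": [1.0, 1.0]},
            index=["0.5-1", "1-2"],
        )

    def test_zero_efficiency_zero_reads(self, small_scenario, rng):
        pool = make_taxon_pool(4, seed=0)
        dropout = next(t for t in pool if t.amp_efficiency["V4"] == 0)
        bm = pd.DataFrame({t.name: [1.0] for t in pool}, index=["0.5-1"])
        tab = simulate_reads(bm, pool, "V4", small_scenario, rng, station="S1", depth=10_000)
        reads_of = tab.counts.sum(axis=1).groupby(tab.lineages).sum()
        assert not any(dropout.lineage["family"] in lin for lin in reads_of[reads_of > 0].index)

    def test_column_sums_equal_depth(self, small_scenario, rng):
        pool = make_taxon_pool(4, seed=0)
        bm = pd.DataFrame({t.name: [1.0, 2.0] for t in pool}, index=["0.5-1", "1-2"])
        tab = simulate_reads(bm, pool, "COI", small_scenario, rng, station="S1", depth=50_000)
        injected = tab.counts.attrs["injected_singletons"]
        assert tab.total_reads == 2 * 50_000 + injected

    def test_depth_positive(self, small_scenario, rng):
        pool = make_taxon_pool(2, seed=0)
        bm = pd.DataFrame({t.name: [1.0] for t in pool}, index=["0.5-1"])
        with pytest.raises(ValueError):
            simulate_reads(bm, pool, "COI", small_scenario, rng, station="S1", depth=0)

    def test_biomass_ratio_reflected_in_reads(self, rng):
        # 3:1 dry mass at equal efficiency -> mean read ratio 3 within 3 s.e.
        pool = make_taxon_pool(2, seed=0, equal_efficiency=True)
        scenario = default_scenario(seed=0, n_stations=2, singletons_per_fraction=(0, 0))
        bm = pd.DataFrame({pool[0].name: [3.0], pool[1].name: [1.0]}, index=["0.5-1"])
        depth, n_rep = 100_000, 1000
        fracs = []
        for _ in range(n_rep):
            tab = simulate_reads(bm, pool, "COI", scenario, rng, station="S1", depth=depth)
            by_taxon = tab.counts.sum(axis=1).groupby(
                tab.lineages.str.contains("giganteus")
            ).sum()
            fracs.append(by_taxon.get(True, 0) / depth)
        p = 0.75
        se = math.sqrt(p * (1 - p) / depth / n_rep)
        assert abs(np.mean(fracs) - p) < 3 * se

    def test_lineage_truncated_to_marker_resolution(self, small_scenario, rng):
        pool = make_taxon_pool(6, seed=1)
        bm = pd.DataFrame({t.name: [1.0] for t in pool}, index=["0.5-1"])
        tab = simulate_reads(bm, pool, "V9", small_scenario, rng, station="S1", depth=10_000)
        from zoopkit.taxonomy import lineage_depth, parse_lineage, rank_index

        res = {t.name: t.resolution["V9"] for t in pool}
        assert max(res.values(), key=rank_index) in ("family", "order")
        for lin in tab.lineages:
            assert lineage_depth(parse_lineage(lin)) <= rank_index("family")


class TestGenerateDataset:
    def test_inventory(self, dataset_dir):
        names = {p.name for p in Path(dataset_dir).iterdir()}
        for marker in ("COI", "V4", "V9"):
            assert f"asv_{marker}.tsv" in names
        for f in ("objects.tsv", "env.tsv", "stations.tsv", "truth_density.tsv",
                  "truth_biomass.tsv", "scenario.yaml"):
            assert f in names
        # each marker table covers 12 stations x 4 fractions
        from zoopkit import io

        tab = io.read_asv_table(Path(dataset_dir) / "asv_COI.tsv")
        assert len(tab.stations) == 12
        assert tab.counts.columns.nunique() == 48

    def test_rerun_byte_identical(self, tmp_path):
        scenario = default_scenario(seed=11, n_stations=3)
        generate_dataset(scenario, tmp_path / "a", n_taxa=5)
        generate_dataset(scenario, tmp_path / "b", n_taxa=5)
        for pa in sorted((tmp_path / "a").iterdir()):
            ha = hashlib.md5(pa.read_bytes()).hexdigest()
            hb = hashlib.md5((tmp_path / "b" / pa.name).read_bytes()).hexdigest()
            assert ha == hb, pa.name

    def test_truth_biomass_positive_where_objects(self, dataset_dir):
        from zoopkit import io

        truth = io.read_tsv(Path(dataset_dir) / "truth_biomass.tsv")
        objects = io.read_objects(Path(dataset_dir) / "objects.tsv")
        organisms = objects[objects["status"] == "validated"]
        counts = organisms.pivot_table(
            index="station", columns="taxon", values="object_id", aggfunc="count", fill_value=0
        )
        for st in counts.index:
            for taxon in counts.columns:
                if counts.loc[st, taxon] > 0:
                    assert truth.loc[st, taxon] > 0


def test_biomass_by_fraction_uses_conversion(rng):
    pool = make_taxon_pool(2, seed=0)
    obj = pd.DataFrame(
        {
            "taxon": [pool[0].name],
            "object_major": [2.0],
            "object_minor": [1.0],
            "fraction": ["1-2"],
        }
    )
    bm = biomass_by_fraction(obj, pool)
    expected = (4 / 3) * math.pi * 1.0 * 0.25 * pool[0].conversion_factor
    assert bm.loc["1-2", pool[0].name] == pytest.approx(expected)
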