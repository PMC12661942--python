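import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from zoopkit.stats import nmds, passive_vectors, pca
from zoopkit.stats.ordination import influential_taxa, nmds_stress


class TestPca:
    def _env(self, rng, n=10, p=4):
        return pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"S{i}" for i in range(n)],
            columns=[f"v{j}" for j in range(p)],
        )

    def test_variance_shares_sum_100(self, rng):
        res = pca(self._env(rng))
        assert sum(res.quality["var_explained"].values()) == pytest.approx(100.0)

    def test_axis_variances_non_increasing(self, rng):
        res = pca(self._env(rng))
        shares = list(res.quality["var_explained"].values())
        assert all(a >= b - 1e-12 for a, b in zip(shares, shares[1:]))

    def test_two_correlated_variables(self, rng):
        v = rng.normal(size=12)
        env = pd.DataFrame({"a": v, "b": 3 * v + 1})
        res = pca(env, scale=True)
        assert res.quality["var_explained"]["PC1"] == pytest.approx(100.0)

    def test_duplicated_column_same_leading_subspace(self, rng):
        # hand-built case: one dominant signal + weak noise; duplicating the
        # signal column leaves the leading subspace unchanged up to scaling
        signal = np.linspace(-2, 2, 12)
        env = pd.DataFrame({"v0": signal, "v1": rng.normal(0, 0.05, 12)})
        dup = env.assign(v0b=env["v0"])
        r1 = pca(env, scale=False)
        r2 = pca(dup, scale=False)
        c = np.corrcoef(r1.coords["PC1"], r2.coords["PC1"])[0, 1]
        assert abs(c) > 0.999

    def test_oracle_small_case(self):
        # hand-built 3x2: points on a line y=2x (centered); PC1 captures all
        env = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 2.0, 4.0]})
        res = pca(env, scale=False)
        assert res.quality["var_explained"]["PC1"] == pytest.approx(100.0)
        # scores spacing matches the point spacing along the line
        diffs = np.diff(res.coords["PC1"])
        assert diffs[0] == pytest.approx(diffs[1])

    def test_sign_convention(self, rng):
        res = pca(self._env(rng))
        for ax in res.loadings.columns:
            lead = res.loadings[ax].abs().idxmax()
            assert res.loadings.loc[lead, ax] > 0

    def test_too_few_stations(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame({"a": [1.0]}))

    def test_constant_column_error(self):
        with pytest.raises(ValueError, match="constant"):
            pca(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}))


class TestPassive:
    def test_variable_equal_to_axis1(self, rng):
        env = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = pca(env)
        arrows = passive_vectors(res, pd.DataFrame({"v": res.coords["PC1"]}))
        assert arrows.loc["v", "PC1"] == pytest.approx(1.0)
        assert abs(arrows.loc["v", "PC2"]) < 1e-9

    def test_orthogonalized_variable_near_zero(self, rng):
        env = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        res = pca(env)
        v = rng.normal(size=20)
        scores = res.coords.to_numpy()
        # residualize against all axes -> uncorrelated with each
        beta, *_ = np.linalg.lstsq(scores, v - v.mean(), rcond=None)
        resid = v - v.mean() - scores @ beta
        arrows = passive_vectors(res, pd.DataFrame({"r": resid}, index=res.coords.index),
                                 n_axes=3)
        assert np.abs(arrows.loc["r"]).max() < 1e-9

    def test_passivity(self, rng):
        env = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = pca(env)
        extra1 = pd.DataFrame({"x": rng.normal(size=10)}, index=res.coords.index)
        extra2 = extra1.assign(y=rng.normal(size=10))
        a1 = passive_vectors(res, extra1)
        a2 = passive_vectors(res, extra2)
        pd.testing.assert_series_equal(a1.loc["x"], a2.loc["x"])

    def test_constant_variable_zero_arrow(self, rng):
        env = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = pca(env)
        with pytest.warns(UserWarning, match="W-PASSIVE-CONST"):
            arrows = passive_vectors(res, pd.DataFrame({"c": np.ones(10)},
                                                       index=res.coords.index))
        assert (arrows.loc["c"] == 0).all()


class TestNmds:
    def test_line_embeds_perfectly_in_1d(self):
        x = np.array([[0.0], [1.0], [2.0], [3.5]])
        d = pd.DataFrame(squareform(pdist(x)))
        res = nmds(d, k=1, seed=0)
        assert res.quality["stress"] < 1e-6

    def test_recovers_known_configuration(self, rng):
        x = rng.normal(size=(10, 2))
        d = pd.DataFrame(squareform(pdist(x)))
        res = nmds(d, k=2, seed=0)
        assert res.quality["stress"] < 1e-4
        _, _, disparity = procrustes(x, res.coords.to_numpy())
        assert disparity < 1e-3

    def test_stress_history_non_increasing(self, rng):
        x = rng.normal(size=(9, 4))
        d = pd.DataFrame(squareform(pdist(x)))
        res = nmds(d, k=2, seed=1)
        h = res.quality["stress_history"]
        assert all(b <= a + 1e-15 for a, b in zip(h, h[1:]))

    def test_four_point_oracle_k2(self):
        # four equidistant points cannot embed in 2-D: nonzero optimum
        d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
        res = nmds(d, k=2, seed=0, n_starts=16)

        def stress_of(v):
            return nmds_stress(d.to_numpy(), v.reshape(4, 2))

        best = min(
            minimize(
                stress_of,
                np.random.default_rng(s).normal(size=8),
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-14},
            ).fun
            for s in range(12)
        )
        assert res.quality["stress"] == pytest.approx(best, abs=1e-3)
        assert res.quality["stress"] > 0.01

    def test_four_point_oracle_k1(self):
        d = pd.DataFrame(
            np.array(
                [
                    [0.0, 1.0, 1.2, 0.9],
                    [1.0, 0.0, 1.1, 1.3],
                    [1.2, 1.1, 0.0, 1.0],
                    [0.9, 1.3, 1.0, 0.0],
                ]
            )
        )
        res = nmds(d, k=1, seed=0, n_starts=16)

        def stress_of(v):
            return nmds_stress(d.to_numpy(), v.reshape(4, 1))

        best = min(
            minimize(
                stress_of,
                np.random.default_rng(s).normal(size=4),
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-14},
            ).fun
            for s in range(12)
        )
        assert res.quality["stress"] == pytest.approx(best, abs=1e-3)

    def test_stress_in_unit_interval(self, rng):
        m = rng.uniform(0.2, 1.0, (7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        res = nmds(pd.DataFrame(m), k=2, seed=3)
        assert 0 <= res.quality["stress"] <= 1

    def test_non_symmetric_rejected(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            nmds(bad)

    def test_nonzero_diagonal_rejected(self):
        bad = pd.DataFrame([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            nmds(bad)

    def test_tie_treatments_both_run(self, rng):
        m = rng.integers(1, 4, (6, 6)).astype(float)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        for ties in ("average", "break"):
            res = nmds(pd.DataFrame(m), k=2, seed=0, ties=ties)
            assert np.isfinite(res.quality["stress"])

    def test_determinism(self, rng):
        m = rng.uniform(0.2, 1.0, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        r1 = nmds(pd.DataFrame(m), k=2, seed=5)
        r2 = nmds(pd.DataFrame(m), k=2, seed=5)
        pd.testing.assert_frame_equal(r1.coords, r2.coords)


class TestInfluential:
    def _setup(self, rng):
        coords = pd.DataFrame(
            {"NMDS1": [1.0, -1.0, 0.5], "NMDS2": [0.0, 0.5, -0.5]},
            index=["S1", "S2", "S3"],
        )
        from zoopkit.stats.ordination import OrdinationResult

        ordn = OrdinationResult(method="nMDS", coords=coords, quality={"stress": 0.0})
        return ordn

    def test_single_station_taxon_at_station(self, rng):
        ordn = self._setup(rng)
        m = pd.DataFrame(
            {"t1": [5.0, 0.0, 0.0], "t2": [1.0, 1.0, 1.0]},
            index=["S1", "S2", "S3"],
        )
        out = influential_taxa(m, ordn, k=10).set_index("taxon")
        assert out.loc["t1", "NMDS1"] == pytest.approx(1.0)
        assert out.loc["t1", "NMDS2"] == pytest.approx(0.0)

    def test_uniform_taxon_at_centroid(self, rng):
        ordn = self._setup(rng)
        ordn.coords -= ordn.coords.mean()  # centered ordination
        m = pd.DataFrame({"u": [2.0, 2.0, 2.0]}, index=["S1", "S2", "S3"])
        out = influential_taxa(m, ordn, k=1).set_index("taxon")
        assert abs(out.loc["u", "NMDS1"]) < 1e-12

    def test_relabeling_stable(self, rng):
        ordn = self._setup(rng)
        m = pd.DataFrame(
            rng.uniform(0, 3, (3, 6)),
            index=["S1", "S2", "S3"],
            columns=[f"t{j}" for j in range(6)],
        )
        top = influential_taxa(m, ordn, k=3)["taxon"].tolist()
        perm = m[sorted(m.columns, reverse=True)]
        top2 = influential_taxa(perm, ordn, k=3)["taxon"].tolist()
        assert top == top2
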