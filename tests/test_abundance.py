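import numpy as np
import pandas as pd
import pytest

import coocnet as cn
from coocnet.structure import ModulePartition


def _abund(values, guilds=None):
    df = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(len(values))],
        columns=[f"sp{j}" for j in range(len(values[0]))],
        dtype=float,
    )
    return cn.SiteSpeciesMatrix(
        values=df,
        guild=guilds or {c: "plant" for c in df.columns},
        value_kind="abundance",
    )


def _dist(labels, arr):
    return cn.DistanceMatrix(
        values=pd.DataFrame(np.asarray(arr, dtype=float), index=labels, columns=labels)
    )


class TestHellinger:
    def test_hand_row(self):
        h = cn.hellinger(_abund([[1, 1, 2]]))
        assert np.allclose(h.values.iloc[0], [0.5, 0.5, np.sqrt(0.5)])

    def test_single_species_site(self):
        h = cn.hellinger(_abund([[0, 5, 0]]))
        assert h.values.iloc[0].tolist() == [0.0, 1.0, 0.0]

    def test_rows_unit_sum_of_squares(self):
        rng = np.random.default_rng(1)
        h = cn.hellinger(_abund(rng.gamma(1.0, 2.0, size=(12, 7))))
        assert np.allclose((h.values.to_numpy() ** 2).sum(axis=1), 1.0)

    def test_zero_total_sites_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            h = cn.hellinger(_abund([[1, 1], [0, 0]]))
        assert list(h.values.index) == ["s0"]

    def test_requires_abundance_kind(self, presence_matrix):
        with pytest.raises(cn.DataValidationError):
            cn.hellinger(presence_matrix)


class TestDispersionIndex:
    def test_identical_species_zero_everywhere(self):
        labels = ["sp0", "sp1", "sp2"]
        d = _dist(labels, np.zeros((3, 3)))
        m = _abund([[1, 2, 3], [4, 0, 1]])
        assert np.allclose(cn.dispersion_index(m, d), 0.0)

    def test_two_equidistant_species_half(self):
        labels = ["sp0", "sp1"]
        d = _dist(labels, [[0, 1], [1, 0]])
        m = _abund([[2, 2]])
        assert cn.dispersion_index(m, d).iloc[0] == pytest.approx(0.5)

    def test_abundance_scaling_invariance(self):
        rng = np.random.default_rng(4)
        labels = [f"sp{j}" for j in range(5)]
        raw = rng.random((5, 5))
        arr = (raw + raw.T) / 2
        np.fill_diagonal(arr, 0)
        d = _dist(labels, arr)
        a = rng.gamma(1, 1, size=(6, 5))
        v1 = cn.dispersion_index(_abund(a), d)
        v2 = cn.dispersion_index(_abund(10 * a), d)
        assert np.allclose(v1, v2)

    def test_sites_with_single_species_zero(self):
        labels = ["sp0", "sp1"]
        d = _dist(labels, [[0, 1], [1, 0]])
        m = _abund([[3, 0]])
        assert cn.dispersion_index(m, d).iloc[0] == 0.0

    def test_missing_species_rejected(self):
        d = _dist(["sp0"], [[0.0]])
        with pytest.raises(cn.DataValidationError):
            cn.dispersion_index(_abund([[1, 2]]), d)


class TestDispersionSES:
    def test_constant_distances_degenerate(self):
        labels = [f"sp{j}" for j in range(4)]
        d = _dist(labels, np.ones((4, 4)) - np.eye(4))
        m = _abund(np.random.default_rng(0).gamma(1, 1, size=(8, 4)))
        r = cn.dispersion_ses(m, d, n_perm=99, seed=1)
        assert r.ses is None

    def test_p_strictly_inside_unit_interval(self, small_bundle):
        traits = small_bundle.plant_traits
        d = cn.functional_distance(traits)
        plants = small_bundle.abundance.species_of_guild("plant")
        m = small_bundle.abundance.subset_species(plants)
        r = cn.dispersion_ses(m, d, n_perm=99, seed=2)
        assert 0 < r.p <= 1
        assert r.n_perm == 99

    def test_clustered_dominants_give_negative_ses(self):
        """Dominant species close in trait space pull dispersion below null."""
        rng = np.random.default_rng(5)
        n_sp = 12
        labels = [f"sp{j:02d}" for j in range(n_sp)]
        traits = np.linspace(0, 1, n_sp)
        arr = np.abs(np.subtract.outer(traits, traits))
        d = _dist(labels, arr)
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.gamma(1.0, 0.05, size=(20, n_sp))
            a[:, :4] += rng.gamma(5.0, 2.0, size=(20, 4))  # dominants: sp00-sp03
            df = pd.DataFrame(a, index=[f"s{i}" for i in range(20)], columns=labels)
            m = cn.SiteSpeciesMatrix(
                values=df, guild={c: "plant" for c in labels}, value_kind="abundance"
            )
            r = cn.dispersion_ses(m, d, n_perm=99, seed=seed + 1)
            hits += r.ses is not None and r.ses < 0
        assert hits >= 0.9 * n_seeds


class TestRdaAdjustedR2:
    def test_exact_linear_map_gives_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        Y = X @ rng.normal(size=(3, 5))
        assert cn.rda_adjusted_r2(Y, X) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictors_negative_adjusted(self):
        n = 20
        Y = np.zeros((n, 2))
        Y[:, 0] = np.tile([1, -1], n // 2)
        X = np.ones((n, 1)) * np.arange(n)[:, None]
        X = X - X.mean(axis=0)
        # make X exactly orthogonal to Y
        X[:, 0] -= (X[:, 0] @ Y[:, 0]) / (Y[:, 0] @ Y[:, 0]) * Y[:, 0]
        adj = cn.rda_adjusted_r2(Y, X)
        assert adj < 0

    def test_unbiased_near_zero_for_noise(self):
        rng = np.random.default_rng(42)
        vals = [
            cn.rda_adjusted_r2(rng.normal(size=(48, 6)), rng.normal(size=(48, 3)))
            for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 2))
        X = np.hstack([X, X[:, :1] * 2.0])
        Y = rng.normal(size=(25, 3))
        with pytest.warns(UserWarning, match="collinear"):
            adj = cn.rda_adjusted_r2(Y, X)
        assert np.isfinite(adj)


class TestVariancePartition:
    def _env(self, rng, n):
        idx = [f"s{i}" for i in range(n)]
        return (
            pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=list("abc")),
            pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=list("def")),
            pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=list("ghi")),
        )

    def test_fractions_sum_to_full_model(self):
        rng = np.random.default_rng(0)
        x1, x2, x3 = self._env(rng, 48)
        Y = pd.DataFrame(rng.normal(size=(48, 10)), index=x1.index)
        vp = cn.variance_partition(Y, x1, x2, x3, n_perm=99, seed=1)
        total = sum(vp.fractions[k] for k in "abcdefg")
        assert total == pytest.approx(vp.full_adj_r2, abs=1e-10)

    def test_spatial_only_signal_recovered(self):
        rng = np.random.default_rng(3)
        pure = []
        for _ in range(30):
            x1, x2, x3 = self._env(rng, 48)
            Y = pd.DataFrame(
                x3.to_numpy() @ rng.normal(size=(3, 8)) + 0.5 * rng.normal(size=(48, 8)),
                index=x1.index,
            )
            vp = cn.variance_partition(Y, x1, x2, x3, n_perm=99, seed=5)
            pure.append((vp.fractions["a"], vp.fractions["b"], vp.fractions["c"]))
        pure = np.array(pure)
        assert pure[:, 2].mean() > 0.5  # X3 dominates
        assert abs(pure[:, 0].mean()) < 0.05
        assert abs(pure[:, 1].mean()) < 0.05

    def test_duplicated_sets_move_signal_to_joint(self):
        rng = np.random.default_rng(7)
        x1, _, x3 = self._env(rng, 40)
        x2 = x1.copy()
        x2.columns = list("def")
        Y = pd.DataFrame(
            x1.to_numpy() @ rng.normal(size=(3, 6)) + 0.3 * rng.normal(size=(40, 6)),
            index=x1.index,
        )
        vp = cn.variance_partition(Y, x1, x2, x3, n_perm=99, seed=2)
        assert abs(vp.fractions["a"]) < 0.05
        assert abs(vp.fractions["b"]) < 0.05
        assert vp.fractions["d"] > 0.5  # X1&X2 joint carries it

    def test_pure_fraction_p_values_reported(self):
        rng = np.random.default_rng(9)
        x1, x2, x3 = self._env(rng, 30)
        Y = pd.DataFrame(rng.normal(size=(30, 4)), index=x1.index)
        vp = cn.variance_partition(Y, x1, x2, x3, n_perm=99, seed=3)
        assert set(vp.pure_p) == {"a", "b", "c"}
        assert all(0 < p <= 1 for p in vp.pure_p.values())


class TestSubsetByModule:
    def test_column_sets(self):
        m = _abund(np.ones((3, 6)))
        p = ModulePartition(
            membership={f"sp{j}": 1 if j < 3 else 2 for j in range(6)}, q=0.0
        )
        subsets = cn.subset_by_module(m, p)
        assert sorted(subsets[1].species_ids) == ["sp0", "sp1", "sp2"]
        assert sorted(subsets[2].species_ids) == ["sp3", "sp4", "sp5"]
        union = sorted(s for sub in subsets.values() for s in sub.species_ids)
        assert union == sorted(p.membership)

    def test_missing_species_named_in_error(self):
        m = _abund(np.ones((3, 2)))
        p = ModulePartition(membership={"sp0": 1, "spX": 1}, q=0.0)
        with pytest.raises(cn.DataValidationError, match="spX"):
            cn.subset_by_module(m, p)
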