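import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, kstest

import coocnet as cn
from coocnet.assembly import benjamini_hochberg
from coocnet.structure import ModulePartition


def _dist(labels, arr):
    return cn.DistanceMatrix(
        values=pd.DataFrame(np.asarray(arr, dtype=float), index=labels, columns=labels)
    )


def _partition(mapping):
    return ModulePartition(membership=dict(mapping), q=0.0)


class TestModuleMeanDistance:
    def test_pair_module(self):
        d = _dist(["A", "B"], [[0, 0.4], [0.4, 0]])
        p = _partition({"A": 1, "B": 1})
        assert cn.module_mean_distance(p, d, ["A", "B"])[1] == pytest.approx(0.4)

    def test_triple_module_arithmetic_mean(self):
        d = _dist(
            ["A", "B", "C"],
            [[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]],
        )
        p = _partition({"A": 1, "B": 1, "C": 1})
        assert cn.module_mean_distance(p, d, ["A", "B", "C"])[1] == pytest.approx(0.4)

    def test_identical_trait_module_zero(self):
        d = _dist(["A", "B", "C"], np.zeros((3, 3)))
        p = _partition({"A": 1, "B": 1, "C": 1})
        assert cn.module_mean_distance(p, d, ["A", "B", "C"])[1] == 0.0

    def test_singleton_module_undefined(self):
        d = _dist(["A", "B"], [[0, 1], [1, 0]])
        p = _partition({"A": 1, "B": 2})
        means = cn.module_mean_distance(p, d, ["A", "B"])
        assert means[1] is None and means[2] is None

    def test_invariant_to_species_relabeling(self):
        rng = np.random.default_rng(0)
        n = 8
        raw = rng.random((n, n))
        arr = (raw + raw.T) / 2
        np.fill_diagonal(arr, 0)
        labels = [f"s{i}" for i in range(n)]
        d1 = _dist(labels, arr)
        p1 = _partition({s: 1 if i < 4 else 2 for i, s in enumerate(labels)})
        renamed = [f"x{i}" for i in range(n)]
        d2 = cn.DistanceMatrix(
            values=pd.DataFrame(arr, index=renamed, columns=renamed)
        )
        p2 = _partition({s: 1 if i < 4 else 2 for i, s in enumerate(renamed)})
        m1 = cn.module_mean_distance(p1, d1, labels)
        m2 = cn.module_mean_distance(p2, d2, renamed)
        assert m1[1] == pytest.approx(m2[1]) and m1[2] == pytest.approx(m2[2])


class TestModuleDistanceSES:
    def _convergent_setup(self, seed, n_species=40, n_modules=5, sd_within=0.1):
        rng = np.random.default_rng(seed)
        labels = [f"s{i:02d}" for i in range(n_species)]
        module = {s: (i % n_modules) + 1 for i, s in enumerate(labels)}
        traits = np.empty(n_species)
        for i, s in enumerate(labels):
            if module[s] == 1:
                traits[i] = rng.normal(0.0, sd_within)
            else:
                traits[i] = rng.normal(0.0, 1.0)
        arr = np.abs(np.subtract.outer(traits, traits))
        return _partition(module), _dist(labels, arr), labels

    def test_convergent_module_detected(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            p, d, labels = self._convergent_setup(seed)
            res = {r.module: r for r in cn.module_distance_ses(p, d, labels, n_perm=199, seed=seed)}
            hits += res[1].ses is not None and res[1].ses < -1.96
        assert hits >= 0.9 * n_seeds

    def test_neutral_p_uniform(self):
        pvals = []
        for seed in range(150):
            rng = np.random.default_rng(seed + 10_000)
            labels = [f"s{i:02d}" for i in range(30)]
            traits = rng.normal(size=30)
            arr = np.abs(np.subtract.outer(traits, traits))
            p = _partition({s: (i % 3) + 1 for i, s in enumerate(labels)})
            res = cn.module_distance_ses(p, _dist(labels, arr), labels, n_perm=199, seed=seed)
            pvals.append(res[0].p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_equal_distances_degenerate(self):
        labels = ["A", "B", "C", "D"]
        arr = np.ones((4, 4)) - np.eye(4)
        p = _partition({"A": 1, "B": 1, "C": 2, "D": 2})
        res = cn.module_distance_ses(p, _dist(labels, arr), labels, n_perm=99, seed=0)
        for r in res:
            assert r.ses is None

    def test_small_modules_not_testable(self):
        labels = ["A", "B", "C"]
        arr = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        p = _partition({"A": 1, "B": 1, "C": 2})
        res = {r.module: r for r in cn.module_distance_ses(p, _dist(labels, arr), labels, n_perm=99, seed=0)}
        assert res[2].testable is False and res[2].p is None

    def test_null_preserves_module_sizes(self):
        # per-module null distributions exist exactly for the observed sizes
        p, d, labels = self._convergent_setup(0)
        res = cn.module_distance_ses(p, d, labels, n_perm=99, seed=1)
        assert sorted(r.n_species for r in res) == [8] * 5

    def test_modules_scored_independently(self):
        # duplicating a module's membership does not change another's result
        p, d, labels = self._convergent_setup(3)
        res_all = {r.module: r for r in cn.module_distance_ses(p, d, labels, n_perm=199, seed=5)}
        assert res_all[2].p is not None and res_all[3].p is not None


class TestTraitShifts:
    def _traits(self, values, kind):
        df = pd.DataFrame({"t": values})
        df.index = [f"s{i}" for i in range(len(values))]
        return cn.TraitTable(values=df.astype(float), trait_kind={"t": kind})

    def test_identical_distributions_kw_zero(self):
        t = self._traits([1, 2, 3, 1, 2, 3], "continuous")
        p = _partition({f"s{i}": 1 if i < 3 else 2 for i in range(6)})
        (r,) = cn.trait_shift_tests(t, p, list(t.species_ids))
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_kw_hand_computed_value(self):
        # ranks 1..6 split (1,2,3) vs (4,5,6): H = 12/42 * (36/3 + 225/3) - 21
        t = self._traits([1, 2, 3, 4, 5, 6], "continuous")
        p = _partition({f"s{i}": 1 if i < 3 else 2 for i in range(6)})
        (r,) = cn.trait_shift_tests(t, p, list(t.species_ids))
        assert r.test == "kruskal-wallis"
        assert r.statistic == pytest.approx(3.857, abs=1e-3)
        assert r.p == pytest.approx(0.0495, abs=1e-3)

    def test_binary_trait_uses_exact_test(self):
        t = self._traits([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], "binary")
        p = _partition({f"s{i}": 1 if i < 5 else 2 for i in range(10)})
        (r,) = cn.trait_shift_tests(t, p, list(t.species_ids))
        assert r.test == "fisher-exact"
        assert r.p == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_constant_trait_skipped(self):
        t = self._traits([1, 1, 1, 1], "binary")
        p = _partition({f"s{i}": 1 if i < 2 else 2 for i in range(4)})
        (r,) = cn.trait_shift_tests(t, p, list(t.species_ids))
        assert r.test == "skipped"


class TestFisherExactRxc:
    def test_perfect_segregation_2x2(self):
        assert cn.fisher_exact_rxc(np.array([[5, 0], [0, 5]])) == pytest.approx(
            2 / math.comb(10, 5), rel=1e-9
        )

    def test_matches_scipy_on_random_2x2(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = rng.integers(0, 8, size=(2, 2))
            if table.sum() == 0:
                continue
            ours = cn.fisher_exact_rxc(table)
            ref = fisher_exact(table).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_three_by_two_enumeration(self):
        # uniform table: no evidence of dependence
        p = cn.fisher_exact_rxc(np.array([[2, 2], [2, 2], [2, 2]]))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_strong_dependence_small_p(self):
        p = cn.fisher_exact_rxc(np.array([[6, 0], [0, 6], [3, 3]]))
        assert p < 0.05


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.02, 0.03, 0.5, 0.9])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
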