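import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import coocnet as cn
from coocnet.cooccur import EmptyNetworkError, retained_species_report


def brute_force_pmf(N, N1, N2):
    """Enumerate every placement of two species over N sites."""
    sites = range(N)
    counts = np.zeros(min(N1, N2) + 1)
    total = 0
    for occ1 in itertools.combinations(sites, N1):
        s1 = set(occ1)
        for occ2 in itertools.combinations(sites, N2):
            counts[len(s1 & set(occ2))] += 1
            total += 1
    return counts / total


class TestPairPmf:
    def test_two_sites_single_occupancy(self):
        assert np.allclose(cn.pair_pmf(2, 1, 1), [0.5, 0.5])

    def test_small_case_matches_enumeration(self):
        pmf = cn.pair_pmf(5, 2, 3)
        assert pmf[2] == pytest.approx(0.3, abs=1e-12)
        assert np.allclose(pmf, brute_force_pmf(5, 2, 3), atol=1e-12)

    def test_ubiquitous_species_fully_overlaps(self):
        pmf = cn.pair_pmf(10, 10, 4)
        assert pmf[4] == pytest.approx(1.0)
        assert np.all(pmf[:4] == 0)

    @pytest.mark.parametrize("N", [3, 5, 8])
    def test_matches_brute_force_all_occupancies(self, N):
        for N1 in range(N + 1):
            for N2 in range(N + 1):
                assert np.allclose(
                    cn.pair_pmf(N, N1, N2), brute_force_pmf(N, N1, N2), atol=1e-12
                ), (N, N1, N2)

    def test_matches_scipy_hypergeom_large_n(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            N = int(rng.integers(10, 201))
            N1 = int(rng.integers(0, N + 1))
            N2 = int(rng.integers(0, N + 1))
            pmf = cn.pair_pmf(N, N1, N2)
            ref = hypergeom.pmf(np.arange(len(pmf)), N, N1, N2)
            assert np.allclose(pmf, ref, atol=1e-12)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            cn.pair_pmf(5, 6, 2)


def _presence(values, guilds=None):
    df = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(len(values))],
        columns=[f"sp{j}" for j in range(len(values[0]))],
        dtype=float,
    )
    return cn.SiteSpeciesMatrix(
        values=df,
        guild=guilds or {c: "plant" for c in df.columns},
        value_kind="presence",
    )


class TestClassifyPairs:
    def test_ubiquitous_pair_is_random(self):
        m = _presence(np.ones((10, 2)))
        (pair,) = cn.classify_pairs(m)
        assert pair.classification == "random"
        assert pair.p_gt == pytest.approx(1.0)

    def test_perfectly_segregated_pair_negative(self):
        # N=20 sites, each species in 10, never together
        values = np.zeros((20, 2))
        values[:10, 0] = 1
        values[10:, 1] = 1
        (pair,) = cn.classify_pairs(_presence(values))
        assert pair.classification == "negative"
        assert pair.p_lt == pytest.approx(1.0 / math.comb(20, 10), rel=1e-9)

    def test_tails_share_atom(self, small_bundle):
        pairs = cn.classify_pairs(small_bundle.presence)
        for p in pairs[:200]:
            if p.classification != "untestable":
                assert p.p_lt + p.p_gt >= 1.0 - 1e-12

    def test_tail_complement_identity(self):
        # P(J >= j) == 1 - P(J <= j-1)
        pmf = cn.pair_pmf(30, 12, 9)
        cdf = np.cumsum(pmf)
        for j in range(1, len(pmf)):
            assert pmf[j:].sum() == pytest.approx(1 - cdf[j - 1], abs=1e-12)

    def test_symmetry_in_species_order(self, presence_matrix):
        pairs = {frozenset((p.species_a, p.species_b)): p for p in cn.classify_pairs(presence_matrix)}
        reversed_cols = presence_matrix.values[presence_matrix.species_ids[::-1]]
        m2 = cn.SiteSpeciesMatrix(
            values=reversed_cols, guild=presence_matrix.guild, value_kind="presence"
        )
        for p in cn.classify_pairs(m2):
            q = pairs[frozenset((p.species_a, p.species_b))]
            assert (p.p_lt, p.p_gt, p.classification) == (q.p_lt, q.p_gt, q.classification)

    def test_absent_species_untestable(self):
        values = np.ones((6, 2))
        values[:, 1] = 0
        (pair,) = cn.classify_pairs(_presence(values))
        assert pair.classification == "untestable"

    def test_low_expectation_untestable(self):
        values = np.zeros((30, 2))
        values[0, 0] = 1
        values[1, 1] = 1
        (pair,) = cn.classify_pairs(_presence(values), min_expected=1.0)
        assert pair.classification == "untestable"

    def test_monte_carlo_site_resampling_agrees(self):
        """Tail probabilities match resampling of site labels (1e5 draws)."""
        rng = np.random.default_rng(11)
        N, N1, N2 = 24, 10, 13
        values = np.zeros((N, 2))
        values[:N1, 0] = 1
        values[:N2, 1] = 1  # j_obs = 10
        (pair,) = cn.classify_pairs(_presence(values), min_expected=0)
        draws = 100_000
        a = values[:, 0].astype(bool)
        joint = np.empty(draws)
        perms = np.argsort(rng.random((draws, N)), axis=1)
        b = values[:, 1][perms]
        joint = b[:, a].sum(axis=1)
        for prob, flag in ((pair.p_gt, joint >= pair.j_obs), (pair.p_lt, joint <= pair.j_obs)):
            est = flag.mean()
            se = math.sqrt(max(prob * (1 - prob), 1e-12) / draws)
            assert abs(est - prob) < 3 * se + 1e-9


class TestBuildNetwork:
    def test_positive_pairs_only_and_filtering(self, presence_matrix):
        pairs = cn.classify_pairs(presence_matrix)
        # force classifications to exercise the filter
        pairs[0].classification = "positive"
        for p in pairs[1:]:
            p.classification = "random"
        net = cn.build_network(pairs)
        assert net.number_of_edges() == 1
        assert set(net.nodes) == {pairs[0].species_a, pairs[0].species_b}

    def test_all_random_raises_empty_network(self, presence_matrix):
        pairs = cn.classify_pairs(presence_matrix)
        for p in pairs:
            p.classification = "random"
        with pytest.raises(EmptyNetworkError):
            cn.build_network(pairs)

    def test_edge_count_equals_positive_count(self, small_bundle):
        pairs = cn.classify_pairs(small_bundle.presence)
        net = cn.build_network(pairs, small_bundle.presence.guild)
        assert net.number_of_edges() == sum(p.classification == "positive" for p in pairs)
        assert all(d > 0 for _, d in net.degree)  # no isolated vertices

    def test_planted_block_forms_clique(self):
        """5 always-co-occurring species vs 5 independent ones, 40 sites."""
        rng = np.random.default_rng(5)
        block_sites = rng.random(40) < 0.5
        values = np.zeros((40, 10))
        values[block_sites, :5] = 1
        values[:, 5:] = rng.random((40, 5)) < 0.5
        net = cn.build_network(cn.classify_pairs(_presence(values)))
        block = [f"sp{j}" for j in range(5)]
        for a, b in itertools.combinations(block, 2):
            assert net.has_edge(a, b)

    def test_retained_report_counts(self, small_bundle):
        pairs = cn.classify_pairs(small_bundle.presence)
        net = cn.build_network(pairs, small_bundle.presence.guild)
        rep = retained_species_report(pairs, small_bundle.presence.guild)
        assert sum(v["retained"] for v in rep.values()) == net.number_of_nodes()
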