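import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coocnet as cn


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale synthetic bundle used across the suite."""
    s = cn.SyntheticScenario(n_sites=24, n_plants=40, n_orthopterans=8, seed=1)
    return cn.generate_bundle(s)


@pytest.fixture(scope="session")
def small_net(small_bundle):
    pairs = cn.classify_pairs(small_bundle.presence)
    return cn.build_network(pairs, small_bundle.presence.guild)


@pytest.fixture
def two_triangles():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")])
    return g


@pytest.fixture
def bridge_graph():
    """Two triangles joined through a degree-2 bridge vertex."""
    return nx.Graph(
        [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
         ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
         ("a3", "x"), ("x", "b1")]
    )


@pytest.fixture
def presence_matrix():
    values = pd.DataFrame(
        [[1, 0, 1], [0, 1, 1], [1, 1, 0], [1, 1, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C"],
        dtype=float,
    )
    guild = {"A": "plant", "B": "plant", "C": "orthopteran"}
    return cn.SiteSpeciesMatrix(values=values, guild=guild, value_kind="presence")


def exhaustive_best_q(g: nx.Graph) -> float:
    """Brute-force maximum modularity over all vertex set partitions."""
    from coocnet.structure import newman_q

    def partitions(items):
        if len(items) == 1:
            yield [items]
            return
        first = items[0]
        for smaller in partitions(items[1:]):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
            yield [[first]] + smaller

    best = -1.0
    for part in partitions(sorted(g.nodes)):
        membership = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, newman_q(g, membership))
    return best


def brute_force_nodf(mat: np.ndarray) -> float:
    """Independently coded NODF: explicit loop over all row and column pairs."""
    mat = np.asarray(mat, dtype=float)
    total, pairs = 0.0, 0
    for axis_mat in (mat, mat.T):
        n = axis_mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                fi, fj = axis_mat[i].sum(), axis_mat[j].sum()
                if fi == fj:
                    continue
                hi, lo = (i, j) if fi > fj else (j, i)
                if axis_mat[lo].sum() == 0:
                    continue
                shared = float((axis_mat[hi] * axis_mat[lo]).sum())
                total += shared / axis_mat[lo].sum()
    return total / pairs if pairs else 0.0
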