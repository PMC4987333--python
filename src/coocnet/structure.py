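"""Modularity and nestedness of the co-occurrence network.

Module detection is the fast-greedy agglomerative maximization of Newman's
Q (merging, from singletons, the community pair with the largest modularity
gain and keeping the partition at peak Q); nestedness is the NODF paired
overlap and decreasing fill index of the binary adjacency, rescaled to
[0, 1] so that 1 is perfect nestedness and 0 no nested structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np


@dataclass
class ModulePartition:
    """Species -> module assignment (module ids contiguous from 1) with Q."""

    membership: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def module_species(self, module: int) -> list[str]:
        return sorted(s for s, m in self.membership.items() if m == module)

    def modules(self) -> list[int]:
        return sorted(set(self.membership.values()))


def newman_q(net: nx.Graph, membership: dict[str, int]) -> float:
    """Newman's modularity Q = sum_c (e_cc - a_c^2).

    e_cc is the fraction of edges with both ends in module c and a_c the
    fraction of edge ends attached to c.
    """
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    missing = [v for v in net.nodes if v not in membership]
    if missing:
        raise ValueError(f"vertices without module assignment: {missing[:5]}")
    modules = set(membership[v] for v in net.nodes)
    e = dict.fromkeys(modules, 0.0)
    a = dict.fromkeys(modules, 0.0)
    for u, v in net.edges:
        cu, cv = membership[u], membership[v]
        if cu == cv:
            e[cu] += 1.0
        a[cu] += 1.0
        a[cv] += 1.0
    return sum(e[c] / m - (a[c] / (2.0 * m)) ** 2 for c in modules)


def _canonical_membership(nodes: list[str], labels: list[int]) -> dict[str, int]:
    """Relabel modules 1..k ordered by (size desc, smallest member label)."""
    groups: dict[int, list[str]] = {}
    for node, lab in zip(nodes, labels):
        groups.setdefault(lab, []).append(node)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    out: dict[str, int] = {}
    for new_id, members in enumerate(ordered, start=1):
        for s in members:
            out[s] = new_id
    return out


def greedy_modules(net: nx.Graph, seed: int | None = None) -> ModulePartition:
    """Fast-greedy agglomerative module detection at peak Q.

    Deterministic: the merge order is fixed by the implementation, so
    ``seed`` is accepted for interface symmetry but unused.
    """
    if net.number_of_edges() == 0:
        raise ValueError("module detection is undefined for an edgeless network")
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    clustering = g.community_fastgreedy().as_clustering()
    membership = _canonical_membership(nodes, list(clustering.membership))
    return ModulePartition(membership=membership, q=newman_q(net, membership))


def nestedness_matrix(mat: np.ndarray) -> float:
    """NODF of a binary matrix, rescaled to [0, 1].

    For every row pair (and column pair) with strictly decreasing marginal
    totals, the paired overlap is the fraction of the sparser row's
    occurrences shared by the denser row; pairs with equal totals score 0.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("need a non-empty 2-D binary matrix")
    if not np.isin(mat, (0.0, 1.0)).all():
        raise ValueError("matrix must be binary")

    def _axis_score(m: np.ndarray) -> tuple[float, int]:
        fills = m.sum(axis=1)
        overlap = m @ m.T
        n = m.shape[0]
        lo = np.minimum.outer(fills, fills)
        valid = (np.not_equal.outer(fills, fills)) & (lo > 0)
        contrib = np.where(valid, overlap / np.maximum(lo, 1.0), 0.0)
        iu = np.triu_indices(n, 1)
        return float(contrib[iu].sum()), n * (n - 1) // 2

    rows_total, rows_pairs = _axis_score(mat)
    cols_total, cols_pairs = _axis_score(mat.T)
    denom = rows_pairs + cols_pairs
    if denom == 0:
        return 0.0
    return (rows_total + cols_total) / denom


def nestedness(net: nx.Graph) -> float:
    """NODF nestedness of the network's binary adjacency, in [0, 1]."""
    if net.number_of_nodes() < 2:
        raise ValueError("nestedness needs at least 2 vertices")
    nodes = sorted(net.nodes)
    adj = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    adj = (adj > 0).astype(float)
    return nestedness_matrix(adj)
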