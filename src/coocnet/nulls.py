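"""Fixed-marginal randomizations of the co-occurrence network and SES tests.

The null family randomizes the symmetric 0/1 adjacency while holding its row
and column sums (the degree sequence) fixed:

``swap``
    sequential 2x2 checkerboard swaps (double edge swaps) on the upper
    triangle, mirrored symmetrically; a step is a *successful* swap.
``tswap``
    trial swaps: a step is an *attempted* swap whether or not it can be
    applied, which removes the bias of the plain swap chain toward graphs
    with many swappable checkerboards.
``quasiswap``
    an independent fill: random stub pairing with the exact marginals
    (intermediate multigraph), then repaired back to a simple graph by
    checkerboard swaps that never increase the number of self-loops or
    duplicate edges.

All three leave the degree sequence exactly intact and introduce no
self-loops or multi-edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .structure import ModulePartition, greedy_modules, nestedness, nestedness_matrix, newman_q

METHODS = ("swap", "tswap", "quasiswap")


@njit(cache=True)
def _swap_chain(adj, edges, n_steps, count_trials, seed, max_attempts):
    """Run the checkerboard-swap chain in place; returns successful swaps."""
    np.random.seed(seed)
    m = edges.shape[0]
    done = 0
    attempts = 0
    successes = 0
    while done < n_steps and attempts < max_attempts:
        attempts += 1
        if count_trials:
            done = attempts
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, c] = True
        adj[c, a] = True
        adj[b, d] = True
        adj[d, b] = True
        edges[e1, 0], edges[e1, 1] = a, c
        edges[e2, 0], edges[e2, 1] = b, d
        successes += 1
        if not count_trials:
            done = successes
    return successes


@njit(cache=True)
def _quasiswap_fill(deg, seed, max_repair):
    """Random stub pairing with exact marginals, repaired to a simple graph.

    Returns (edges, ok): ok is False when repair did not converge.
    """
    np.random.seed(seed)
    n = deg.shape[0]
    total = 0
    for i in range(n):
        total += deg[i]
    m = total // 2
    stubs = np.empty(total, np.int64)
    pos = 0
    for i in range(n):
        for _ in range(deg[i]):
            stubs[pos] = i
            pos += 1
    for i in range(total - 1, 0, -1):  # Fisher-Yates
        j = np.random.randint(i + 1)
        stubs[i], stubs[j] = stubs[j], stubs[i]
    edges = np.empty((m, 2), np.int64)
    counts = np.zeros((n, n), np.int64)  # counts[i,i] = self-loop count
    for k in range(m):
        a, b = stubs[2 * k], stubs[2 * k + 1]
        edges[k, 0], edges[k, 1] = a, b
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1

    def cell_bad(i, j, c):
        if i == j:
            return c
        if c > 1:
            return c - 1
        return 0

    # indices of currently offending edge instances
    for _ in range(max_repair):
        n_bad = 0
        for k in range(m):
            a, b = edges[k, 0], edges[k, 1]
            if a == b or counts[a, b] > 1:
                n_bad += 1
        if n_bad == 0:
            return edges, True
        pick = np.random.randint(n_bad)
        e1 = -1
        seen = 0
        for k in range(m):
            a, b = edges[k, 0], edges[k, 1]
            if a == b or counts[a, b] > 1:
                if seen == pick:
                    e1 = k
                    break
                seen += 1
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # badness change of (a,b),(c,d) -> (a,c),(b,d), updating cells stepwise
        delta = 0
        delta -= cell_bad(a, b, counts[a, b])
        counts[a, b] -= 1
        if a != b:
            counts[b, a] -= 1
        delta += cell_bad(a, b, counts[a, b])
        delta -= cell_bad(c, d, counts[c, d])
        counts[c, d] -= 1
        if c != d:
            counts[d, c] -= 1
        delta += cell_bad(c, d, counts[c, d])
        delta -= cell_bad(a, c, counts[a, c])
        counts[a, c] += 1
        if a != c:
            counts[c, a] += 1
        delta += cell_bad(a, c, counts[a, c])
        delta -= cell_bad(b, d, counts[b, d])
        counts[b, d] += 1
        if b != d:
            counts[d, b] += 1
        delta += cell_bad(b, d, counts[b, d])
        if delta <= 0:
            edges[e1, 0], edges[e1, 1] = a, c
            edges[e2, 0], edges[e2, 1] = b, d
        else:  # revert
            counts[b, d] -= 1
            if b != d:
                counts[d, b] -= 1
            counts[a, c] -= 1
            if a != c:
                counts[c, a] -= 1
            counts[c, d] += 1
            if c != d:
                counts[d, c] += 1
            counts[a, b] += 1
            if a != b:
                counts[b, a] += 1
    return edges, False


class _EdgeSampler:
    """Degree-preserving randomized edge sets over integer vertex ids."""

    def __init__(
        self,
        n_nodes: int,
        edges: np.ndarray,
        method: str,
        rng: np.random.Generator,
        burn_in: int | None = None,
        thin: int | None = None,
    ):
        if method not in METHODS:
            raise ValueError(f"unknown permutation method {method!r}")
        self.method = method
        self.rng = rng
        self.n = n_nodes
        self.edges = edges.astype(np.int64).copy()
        self.m = self.edges.shape[0]
        self.deg = np.bincount(self.edges.ravel(), minlength=n_nodes).astype(np.int64)
        self.burn_in = 10 * self.m if burn_in is None else int(burn_in)
        self.thin = 5 * self.m if thin is None else int(thin)
        self._warned = False
        if method in ("swap", "tswap"):
            self.adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
            self.adj[self.edges[:, 0], self.edges[:, 1]] = True
            self.adj[self.edges[:, 1], self.edges[:, 0]] = True
            self._run_chain(self.burn_in)

    def _seed(self) -> int:
        return int(self.rng.integers(1, 2**31 - 1))

    def _run_chain(self, steps: int) -> None:
        count_trials = self.method == "tswap"
        cap = steps if count_trials else max(100 * steps, 1000)
        ok = _swap_chain(
            self.adj, self.edges, steps, count_trials, self._seed(), cap
        )
        if ok == 0 and not self._warned:
            warnings.warn(
                "no swappable checkerboard found; graph returned unchanged",
                stacklevel=3,
            )
            self._warned = True

    def sample(self) -> np.ndarray:
        """Next randomized edge array (m, 2); degree sequence preserved."""
        if self.method == "quasiswap":
            for _ in range(10):
                edges, ok = _quasiswap_fill(self.deg, self._seed(), 500 * self.m)
                if ok:
                    return edges
            raise RuntimeError("quasiswap fill failed to converge to a simple graph")
        self._run_chain(self.thin)
        return self.edges.copy()


def permute_adjacency(
    net: nx.Graph,
    method: str = "quasiswap",
    seed: int | np.random.Generator = 0,
    burn_in: int | None = None,
    thin: int | None = None,
) -> nx.Graph:
    """One degree-preserving randomization of an undirected simple graph.

    ``swap``/``tswap`` run a fresh checkerboard-swap chain from the observed
    graph for ``burn_in`` steps (default 10·|E|); ``quasiswap`` draws an
    independent fill. Node labels and guild attributes are retained.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(index[u], index[v]) for u, v in net.edges], dtype=np.int64)
    sampler = _EdgeSampler(len(nodes), edges, method, rng, burn_in=burn_in, thin=thin)
    # swap/tswap chains are burnt in on construction; quasiswap draws fresh
    new_edges = sampler.edges if method in ("swap", "tswap") else sampler.sample()
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[a], nodes[b]) for a, b in new_edges)
    for v, data in net.nodes(data=True):
        out.nodes[v].update(data)
    return out


@dataclass
class NullEnsembleResult:
    """Observed statistic against a fixed-marginal permutation ensemble."""

    statistic: str
    observed: float
    n_perm: int
    null_mean: float
    null_sd: float
    ses: float | None  # None when the null has zero spread
    p: float  # lower-tail quantile p-value, (1 + #{null < obs}) / (1 + n_perm)
    method: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "p": self.p,
            "method": self.method,
            "seed": self.seed,
        }


def _modularity_from_edges(n: int, edges: np.ndarray) -> float:
    g = ig.Graph(n=n, edges=list(map(tuple, edges)))
    cl = g.community_fastgreedy().as_clustering()
    return float(g.modularity(cl.membership))


def _nestedness_from_edges(n: int, edges: np.ndarray) -> float:
    adj = np.zeros((n, n))
    adj[edges[:, 0], edges[:, 1]] = 1.0
    adj[edges[:, 1], edges[:, 0]] = 1.0
    return nestedness_matrix(adj)


def structure_ses(
    net: nx.Graph,
    statistic: str = "modularity",
    n_perm: int = 9999,
    method: str = "quasiswap",
    seed: int = 0,
    burn_in: int | None = None,
    thin: int | None = None,
) -> NullEnsembleResult:
    """SES and p-value for modularity or nestedness against the chosen null.

    The observed statistic is compared with ``n_perm`` degree-preserving
    randomizations; SES = (obs − null mean)/null sd and p is the lower-tail
    quantile with the add-one correction, so p is never 0 or 1.
    """
    if statistic == "modularity":
        observed = greedy_modules(net).q
        stat_fn = _modularity_from_edges
    elif statistic == "nestedness":
        observed = nestedness(net)
        stat_fn = _nestedness_from_edges
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(index[u], index[v]) for u, v in net.edges], dtype=np.int64)
    sampler = _EdgeSampler(len(nodes), edges, method, rng, burn_in=burn_in, thin=thin)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat_fn(len(nodes), sampler.sample())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    mean = float(null.mean())
    ses = (observed - mean) / sd if sd > 0 else None
    p = (1.0 + np.sum(null < observed)) / (1.0 + n_perm)
    return NullEnsembleResult(
        statistic=statistic,
        observed=float(observed),
        n_perm=n_perm,
        null_mean=mean,
        null_sd=sd,
        ses=ses,
        p=float(p),
        method=method,
        seed=seed,
    )


def knockout_importance(
    net: nx.Graph,
    partition: ModulePartition | None = None,
    use_sample_sd: bool = True,
) -> pd.DataFrame:
    """Leave-one-out contribution of each species to modularity and nestedness.

    For species i, Δ_i = (statistic on the full network) − (statistic with i
    removed); SES_i = (Δ_i − mean Δ)/sd Δ. Positive SES means the structure
    degrades when the species is removed (a structural contributor); a
    species whose removal makes the network *more* modular gets a negative
    modularity SES. Removals that leave an edgeless network are flagged with
    NaN and excluded from the standardization.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("knock-out needs at least 3 vertices")
    if partition is None:
        partition = greedy_modules(net)
    q0 = partition.q
    nest0 = nestedness(net)
    rows = []
    for v in sorted(net.nodes):
        sub = net.copy()
        sub.remove_node(v)
        if sub.number_of_edges() == 0 or sub.number_of_nodes() < 2:
            dq = np.nan
            dn = np.nan
        else:
            dq = q0 - greedy_modules(sub).q
            dn = nest0 - nestedness(sub)
        rows.append(
            {
                "species": v,
                "module": partition.membership[v],
                "degree": net.degree[v],
                "delta_q": dq,
                "delta_nestedness": dn,
            }
        )
    df = pd.DataFrame(rows).set_index("species")
    _attach_ses_columns(df, use_sample_sd)
    return df


def _attach_ses_columns(df: pd.DataFrame, use_sample_sd: bool) -> None:
    ddof = 1 if use_sample_sd else 0
    for col, out in (("delta_q", "ses_q"), ("delta_nestedness", "ses_nestedness")):
        x = df[col].to_numpy()
        good = ~np.isnan(x)
        sd = x[good].std(ddof=ddof) if good.sum() > 1 else 0.0
        # all-equal deltas up to float roundoff: SES undefined
        if sd > 1e-12 * max(1.0, np.abs(x[good]).max(initial=0.0)):
            df[out] = np.where(good, (x - x[good].mean()) / sd, np.nan)
        else:
            df[out] = np.nan


# ---------------------------------------------------------------------------
# alternative null: permute the site × species matrix, rebuild the network


@njit(cache=True)
def _matrix_tswap(X, cells, n_trials, seed):
    """Trial checkerboard swaps on a rectangular binary matrix, in place."""
    np.random.seed(seed)
    f = cells.shape[0]
    for _ in range(n_trials):
        i = np.random.randint(f)
        j = np.random.randint(f)
        r1, c1 = cells[i, 0], cells[i, 1]
        r2, c2 = cells[j, 0], cells[j, 1]
        if r1 == r2 or c1 == c2:
            continue
        if X[r1, c2] or X[r2, c1]:
            continue
        X[r1, c1] = False
        X[r2, c2] = False
        X[r1, c2] = True
        X[r2, c1] = True
        cells[i, 1] = c2
        cells[j, 1] = c1


def structure_ses_matrix_null(
    presence,
    statistic: str = "modularity",
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    min_expected: float = 1.0,
):
    """SES against a null that permutes the site × species matrix itself.

    Each draw randomizes the presence matrix with fixed row and column sums
    (trial checkerboard swaps), re-runs the pairwise classification and the
    network build, and recomputes the statistic. Draws whose network is
    empty contribute 0 (no structure). Sensitivity-analysis alternative to
    the default adjacency null; much slower, since the whole pairwise
    classification is redone per draw.
    """
    from .cooccur import EmptyNetworkError, build_network, classify_pairs
    from .datatypes import SiteSpeciesMatrix

    if presence.value_kind != "presence":
        raise ValueError("matrix null needs a presence matrix")

    def stat_of(m) -> float:
        try:
            net = build_network(classify_pairs(m, alpha=alpha, min_expected=min_expected))
        except EmptyNetworkError:
            return 0.0
        if statistic == "modularity":
            return greedy_modules(net).q
        if net.number_of_nodes() < 2:
            return 0.0
        return nestedness(net)

    if statistic not in ("modularity", "nestedness"):
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = stat_of(presence)
    rng = np.random.default_rng(seed)
    X = presence.values.to_numpy(dtype=float) > 0
    cells = np.argwhere(X).astype(np.int64)
    fill = cells.shape[0]
    Xw = X.copy()
    _matrix_tswap(Xw, cells, 10 * fill, int(rng.integers(1, 2**31 - 1)))
    null = np.empty(n_perm)
    for i in range(n_perm):
        _matrix_tswap(Xw, cells, 5 * fill, int(rng.integers(1, 2**31 - 1)))
        m = SiteSpeciesMatrix(
            values=pd.DataFrame(
                Xw.astype(float), index=presence.values.index, columns=presence.values.columns
            ),
            guild=dict(presence.guild),
            value_kind="presence",
        )
        null[i] = stat_of(m)
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    mean = float(null.mean())
    return NullEnsembleResult(
        statistic=statistic,
        observed=float(observed),
        n_perm=n_perm,
        null_mean=mean,
        null_sd=sd,
        ses=(observed - mean) / sd if sd > 0 else None,
        p=float((1.0 + np.sum(null < observed)) / (1.0 + n_perm)),
        method="matrix-tswap",
        seed=seed,
    )


def knockout_importance_from_data(
    presence,
    alpha: float = 0.05,
    min_expected: float = 1.0,
    use_sample_sd: bool = True,
) -> pd.DataFrame:
    """Knock-out that removes species from the raw data, not the network.

    For each network species the presence column is dropped, the pairwise
    classification and network build are re-run, and the leave-one-out
    modularity and nestedness are recomputed. Slower alternative mode to
    :func:`knockout_importance`.
    """
    from .cooccur import EmptyNetworkError, build_network, classify_pairs

    net0 = build_network(
        classify_pairs(presence, alpha=alpha, min_expected=min_expected),
        presence.guild,
    )
    part0 = greedy_modules(net0)
    nest0 = nestedness(net0)
    rows = []
    for v in sorted(net0.nodes):
        reduced = presence.subset_species([s for s in presence.species_ids if s != v])
        try:
            net = build_network(
                classify_pairs(reduced, alpha=alpha, min_expected=min_expected)
            )
            dq = part0.q - greedy_modules(net).q
            dn = nest0 - nestedness(net) if net.number_of_nodes() >= 2 else np.nan
        except EmptyNetworkError:
            dq, dn = np.nan, np.nan
        rows.append(
            {
                "species": v,
                "module": part0.membership[v],
                "degree": net0.degree[v],
                "delta_q": dq,
                "delta_nestedness": dn,
            }
        )
    df = pd.DataFrame(rows).set_index("species")
    _attach_ses_columns(df, use_sample_sd)
    return df
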