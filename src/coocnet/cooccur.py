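"""Probabilistic pairwise co-occurrence classification and network build.

For two species occupying N1 and N2 of N sites, the number of jointly
occupied sites under random, independent placement follows the hypergeometric
law  P(J = j) = C(N1, j) C(N - N1, N2 - j) / C(N, N2).  A pair co-occurs
positively when the upper tail P(J >= j_obs) falls below alpha, negatively
when the lower tail does; both tails include the probability mass at j_obs.
Positive pairs become the edges of the (undirected, mixed-guild)
co-occurrence network; species with no positive pair are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import SiteSpeciesMatrix

CLASSIFICATIONS = ("positive", "negative", "random", "untestable")


def pair_pmf(N: int, N1: int, N2: int) -> np.ndarray:
    """Exact distribution of the joint-occupancy count J.

    Returns P(J = j) for j = 0..min(N1, N2); entries outside the feasible
    range [max(0, N1 + N2 - N), min(N1, N2)] are exactly zero. Computed in
    log-space so large site counts do not overflow.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError(f"infeasible counts N={N}, N1={N1}, N2={N2}")
    j = np.arange(0, min(N1, N2) + 1)
    lo = max(0, N1 + N2 - N)
    feasible = j >= lo
    with np.errstate(divide="ignore"):
        logp = (
            _lchoose(N1, j)
            + _lchoose(N - N1, N2 - j)
            - _lchoose(N, N2)
        )
    pmf = np.where(feasible, np.exp(logp), 0.0)
    # guard against rounding drift; the mass is 1 by construction
    return pmf / pmf.sum()


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


@dataclass
class PairCooccurrence:
    """Exact co-occurrence test result for one unordered species pair."""

    species_a: str
    species_b: str
    N: int
    N1: int
    N2: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    classification: str


def classify_pairs(
    m: SiteSpeciesMatrix, alpha: float = 0.05, min_expected: float = 1.0
) -> list[PairCooccurrence]:
    """Score every unordered species pair (within and between guilds).

    A pair is ``positive`` if P(J >= j_obs) < alpha, ``negative`` if
    P(J <= j_obs) < alpha, ``random`` otherwise; pairs whose expected joint
    count N1*N2/N is below ``min_expected`` (or with an absent species) are
    ``untestable`` and never become edges.
    """
    if m.value_kind != "presence":
        raise ValueError("classify_pairs requires a presence/absence matrix")
    X = m.values.to_numpy(dtype=float)
    n_sites, n_sp = X.shape
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    species = m.species_ids
    occ = X.sum(axis=0).astype(int)
    joint = (X.T @ X).astype(int)

    # one pmf per distinct (N1, N2) occupancy combination, tails by cumsum
    tails: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def tail_pair(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
        key = (min(n1, n2), max(n1, n2))
        if key not in tails:
            pmf = pair_pmf(n_sites, key[0], key[1])
            cdf = np.cumsum(pmf)
            sf_incl = np.cumsum(pmf[::-1])[::-1]  # P(J >= j), includes atom
            tails[key] = (cdf, sf_incl)
        return tails[key]

    out: list[PairCooccurrence] = []
    for i in range(n_sp):
        for k in range(i + 1, n_sp):
            n1, n2 = int(occ[i]), int(occ[k])
            j_obs = int(joint[i, k])
            expected = n1 * n2 / n_sites
            if n1 == 0 or n2 == 0 or expected < min_expected:
                out.append(
                    PairCooccurrence(
                        species[i], species[k], n_sites, n1, n2, j_obs,
                        expected, 1.0, 1.0, "untestable",
                    )
                )
                continue
            cdf, sf = tail_pair(n1, n2)
            p_lt = float(min(cdf[j_obs], 1.0))
            p_gt = float(min(sf[j_obs], 1.0))
            if p_gt < alpha:
                cls = "positive"
            elif p_lt < alpha:
                cls = "negative"
            else:
                cls = "random"
            out.append(
                PairCooccurrence(
                    species[i], species[k], n_sites, n1, n2, j_obs,
                    expected, p_lt, p_gt, cls,
                )
            )
    return out


def pairs_to_frame(pairs: list[PairCooccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_a": p.species_a,
                "species_b": p.species_b,
                "N": p.N,
                "N1": p.N1,
                "N2": p.N2,
                "j_obs": p.j_obs,
                "expected": p.expected,
                "p_lt": p.p_lt,
                "p_gt": p.p_gt,
                "classification": p.classification,
            }
            for p in pairs
        ]
    )


class EmptyNetworkError(RuntimeError):
    """Raised when no species pair shows positive co-occurrence."""


def build_network(
    pairs: list[PairCooccurrence], guild: dict[str, str] | None = None
) -> nx.Graph:
    """Undirected simple graph over positively co-occurring pairs.

    Species without any positive pair are filtered (they never enter the
    graph). Guild labels, when given, are stored as node attributes.
    """
    g = nx.Graph()
    for p in pairs:
        if p.classification == "positive":
            g.add_edge(p.species_a, p.species_b, p_gt=p.p_gt)
    if g.number_of_edges() == 0:
        n_tested = sum(p.classification != "untestable" for p in pairs)
        raise EmptyNetworkError(
            f"no positive co-occurrence among {len(pairs)} pairs "
            f"({n_tested} testable); network is empty"
        )
    if guild is not None:
        nx.set_node_attributes(
            g, {s: guild[s] for s in g.nodes if s in guild}, "guild"
        )
    return g


def retained_species_report(
    pairs: list[PairCooccurrence], guild: dict[str, str]
) -> dict[str, dict[str, int]]:
    """Counts of species kept/filtered by the positive-co-occurrence filter."""
    all_species = sorted({p.species_a for p in pairs} | {p.species_b for p in pairs})
    kept = set()
    for p in pairs:
        if p.classification == "positive":
            kept.add(p.species_a)
            kept.add(p.species_b)
    report: dict[str, dict[str, int]] = {}
    for g in sorted(set(guild.values())):
        total = [s for s in all_species if guild.get(s) == g]
        report[g] = {
            "total": len(total),
            "retained": sum(s in kept for s in total),
        }
    return report
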