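"""Assembly-rule tests inside network modules.

Within each module (and separately per guild) the mean pairwise functional
or phylogenetic distance is compared against a null that randomly reassigns
the guild's species to modules while keeping every module size and the
distance matrix itself fixed. A lower-tail p near 0 signals trait or lineage
convergence (environmental filtering); a p near 1 signals divergence
(limiting similarity). Shifts of individual traits across modules are tested
with Kruskal-Wallis (continuous traits) or an exact contingency-table test
(binary traits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kruskal

from .datatypes import DistanceMatrix, TraitTable
from .structure import ModulePartition


@dataclass
class ModuleDistanceSES:
    module: int
    guild: str
    distance_kind: str
    n_species: int
    observed: float | None
    ses: float | None
    p: float | None
    testable: bool


def module_mean_distance(
    partition: ModulePartition, d: DistanceMatrix, guild_species: list[str]
) -> dict[int, float | None]:
    """Mean within-module pairwise distance over the given guild's species.

    Modules holding fewer than two of the guild's species have no defined
    mean and map to None.
    """
    out: dict[int, float | None] = {}
    for module in partition.modules():
        members = [s for s in partition.module_species(module) if s in guild_species]
        if len(members) < 2:
            out[module] = None
            continue
        sub = d.values.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), 1)
        out[module] = float(sub[iu].mean())
    return out


def module_distance_ses(
    partition: ModulePartition,
    d: DistanceMatrix,
    guild_species: list[str],
    n_perm: int = 9999,
    seed: int = 0,
    distance_kind: str = "functional",
    guild: str = "",
) -> list[ModuleDistanceSES]:
    """SES of within-module mean distances against random reassignment.

    The null jointly reshuffles the guild's species across all modules,
    holding module sizes fixed; lower-tail p = (1 + #{null < obs})/(1 + n).
    """
    species = sorted(s for s in guild_species if s in partition.membership)
    missing = [s for s in species if s not in d.species_ids]
    if missing:
        raise ValueError(f"species missing from distance matrix: {missing[:5]}")
    D = d.values.loc[species, species].to_numpy()
    modules = partition.modules()
    member_idx = {
        mod: np.array(
            [species.index(s) for s in partition.module_species(mod) if s in species],
            dtype=int,
        )
        for mod in modules
    }
    observed = {
        mod: (
            float(D[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].mean())
            if len(idx) >= 2
            else None
        )
        for mod, idx in member_idx.items()
    }
    testable = [mod for mod in modules if len(member_idx[mod]) >= 2]
    rng = np.random.default_rng(seed)
    n_sp = len(species)
    null = {mod: np.empty(n_perm) for mod in testable}
    for it in range(n_perm):
        perm = rng.permutation(n_sp)
        for mod in testable:
            idx = perm[member_idx[mod]]
            sub = D[np.ix_(idx, idx)]
            null[mod][it] = sub[np.triu_indices(len(idx), 1)].mean()
    results = []
    for mod in modules:
        n_mem = len(member_idx[mod])
        if mod not in null:
            results.append(
                ModuleDistanceSES(mod, guild, distance_kind, n_mem, None, None, None, False)
            )
            continue
        obs = observed[mod]
        sd = float(null[mod].std(ddof=1)) if n_perm > 1 else 0.0
        ses = (obs - float(null[mod].mean())) / sd if sd > 0 else None
        p = float((1.0 + np.sum(null[mod] < obs)) / (1.0 + n_perm))
        results.append(
            ModuleDistanceSES(mod, guild, distance_kind, n_mem, obs, ses, p, True)
        )
    return results


def module_ses_frame(results: list[ModuleDistanceSES]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "guild": r.guild,
                "distance_kind": r.distance_kind,
                "n_species": r.n_species,
                "observed": r.observed,
                "ses": r.ses,
                "p": r.p,
                "testable": r.testable,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# trait shifts across modules


@dataclass
class TraitShiftResult:
    trait: str
    test: str  # "kruskal-wallis" or "fisher-exact"
    statistic: float | None
    p: float | None
    note: str = ""


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Exact conditional test of independence for an r×c count table.

    Enumerates every table with the observed margins; the p-value is the
    total conditional (multivariate hypergeometric) probability of tables no
    more probable than the observed one. Intended for the small tables that
    arise from module × trait-value counts.
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("negative counts")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty table")

    lgf = gammaln(np.arange(n + 1) + 1.0)  # log k!
    log_const = lgf[rows].sum() + lgf[cols].sum() - lgf[n]

    def log_prob(t: np.ndarray) -> float:
        return log_const - lgf[t].sum()

    obs_lp = log_prob(table)
    r, c = table.shape
    p_total = 0.0

    def recurse(row: int, remaining_cols: np.ndarray, current: list[np.ndarray]):
        nonlocal p_total
        if row == r - 1:
            last = remaining_cols
            if (last < 0).any():
                return
            t = np.vstack(current + [last])
            lp = log_prob(t)
            if lp <= obs_lp + 1e-9:
                p_total += float(np.exp(lp))
            return
        # enumerate row `row` with total rows[row] within remaining columns
        def fill(col: int, left: int, acc: list[int]):
            if col == c - 1:
                if left <= remaining_cols[col]:
                    rowvec = np.array(acc + [left], dtype=int)
                    recurse(row + 1, remaining_cols - rowvec, current + [rowvec])
                return
            for v in range(min(left, int(remaining_cols[col])) + 1):
                fill(col + 1, left - v, acc + [v])

        fill(0, int(rows[row]), [])

    recurse(0, cols.copy(), [])
    return min(p_total, 1.0)


def trait_shift_tests(
    traits: TraitTable,
    partition: ModulePartition,
    guild_species: list[str],
    min_module_size: int = 1,
) -> list[TraitShiftResult]:
    """Test whether each trait's distribution differs among modules.

    Continuous traits: Kruskal-Wallis across modules with >= 1 guild
    species; binary traits: exact test on the module × trait-value counts.
    Constant traits are skipped with a note.
    """
    species = [s for s in guild_species if s in partition.membership]
    if not species:
        raise ValueError("no guild species in the partition")
    membership = {s: partition.membership[s] for s in species}
    results = []
    for trait in traits.trait_names:
        vals = traits.values[trait]
        groups: dict[int, list[float]] = {}
        for s in species:
            if s in vals.index and not np.isnan(vals.loc[s]):
                groups.setdefault(membership[s], []).append(float(vals.loc[s]))
        groups = {m: g for m, g in groups.items() if len(g) >= min_module_size}
        if len(groups) < 2:
            results.append(
                TraitShiftResult(trait, "skipped", None, None, "fewer than 2 modules with data")
            )
            continue
        flat = [v for g in groups.values() for v in g]
        if len(set(flat)) == 1:
            results.append(
                TraitShiftResult(trait, "skipped", None, None, "trait constant everywhere")
            )
            continue
        if traits.trait_kind[trait] == "continuous":
            stat, p = kruskal(*[groups[m] for m in sorted(groups)])
            results.append(TraitShiftResult(trait, "kruskal-wallis", float(stat), float(p)))
        else:
            mods = sorted(groups)
            table = np.array(
                [[sum(v == 0 for v in groups[m]), sum(v == 1 for v in groups[m])] for m in mods],
                dtype=int,
            )
            p = fisher_exact_rxc(table)
            results.append(TraitShiftResult(trait, "fisher-exact", None, float(p)))
    return results


def trait_shift_frame(results: list[TraitShiftResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "test": r.test,
                "statistic": r.statistic,
                "p": r.p,
                "note": r.note,
            }
            for r in results
        ]
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (reported alongside raw p, not used for flags)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
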