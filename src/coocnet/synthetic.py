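"""Synthetic grassland community bundles with planted, known structure.

The generator emulates the shape of the study system the pipeline targets:
48 grassland sites, two guilds (~200 vascular plants, ~20 orthopterans),
five co-occurrence modules. Sites belong to clusters matched 1:1 with
modules; a species of module k occurs at cluster-k sites with probability
``p_in`` and elsewhere with ``p_out``, which plants positive within-module
co-occurrence. Traits follow per-module regimes (convergent, divergent,
neutral), phylogenies are pure-birth ultrametric trees with optional
Brownian trait evolution, and three environmental variable sets (practices,
soil, space) can be wired to drive the abundances of chosen modules.

Ground-truth labels (species -> planted module, site -> cluster, regime and
driver maps) travel alongside the data but are never consumed by the
analysis modules, which only accept the plain data containers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .datatypes import EnvTables, SiteSpeciesMatrix, TraitTable
from .phylo import PhyloTree

PLANT_TRAITS = ("Hmax", "LDMC", "Seed_mass", "SLA")  # continuous
ORTHOPTERAN_TRAITS = ("Habitat", "Dispersal", "Feed_change", "Egg_deposition")  # binary

X1_VARS = ("cutting", "grazing", "fertilizers")
X2_VARS = ("total_N", "C_N", "CEC")
X3_VARS = ("longitude", "latitude", "elevation")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study; the defaults mirror the target
    system's scale (48 sites, 197 plants, 22 orthopterans, 5 modules)."""

    n_sites: int = 48
    n_plants: int = 197
    n_orthopterans: int = 22
    n_modules: int = 5
    p_in: float = 0.7
    p_out: float = 0.05
    #: per-module trait regime for the continuous (plant) traits
    regimes: dict[int, str] = field(
        default_factory=lambda: {1: "neutral", 2: "neutral", 3: "divergent",
                                 4: "convergent", 5: "divergent"}
    )
    sd_within: float = 0.1  # convergent regime: within-module trait sd
    divergent_spread: float = 4.0  # divergent regime: range of spaced values
    #: modules whose orthopterans exist at all (others get none),
    #: concentrating the sparse guild in a few modules
    orthopteran_modules: tuple[int, ...] = (1, 2, 4)
    phylo_signal: bool = False  # tips clustered by module when True
    #: which explanatory set drives which modules' abundances
    driven_modules: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"X1": (2, 4, 5), "X2": (), "X3": (1, 2, 3, 4, 5)}
    )
    env_effect: float = 2.0  # sd of per-species log-abundance slopes on drivers
    cluster_shift: float = 1.0  # cluster-mean offset of driving variables
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for mod in range(1, self.n_modules + 1):
            self.regimes.setdefault(mod, "neutral")
        in_sites = self.n_sites // self.n_modules
        out_sites = self.n_sites - in_sites
        if self.p_in * in_sites + self.p_out * out_sites < 2:
            raise ValueError("expected occupancy below 2 sites; scenario rejected")


@dataclass
class SyntheticBundle:
    """A complete synthetic dataset plus its generating ground truth."""

    scenario: SyntheticScenario
    presence: SiteSpeciesMatrix
    abundance: SiteSpeciesMatrix
    plant_traits: TraitTable
    orthopteran_traits: TraitTable
    plant_tree: PhyloTree
    orthopteran_tree: PhyloTree
    env: EnvTables
    species_module: dict[str, int]
    site_cluster: dict[str, int]


def _partition_evenly(items: list[str], n_groups: int) -> dict[str, int]:
    """Round-robin split so group sizes differ by at most one."""
    return {s: (i % n_groups) + 1 for i, s in enumerate(items)}


def generate_occurrence(
    s: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[SiteSpeciesMatrix, dict[str, int], dict[str, int]]:
    """Planted-module presence/absence matrix with ground-truth labels.

    Returns (matrix, species -> module, site -> cluster).
    """
    if rng is None:
        rng = np.random.default_rng(s.seed)
    sites = [f"S{i + 1:02d}" for i in range(s.n_sites)]
    plants = [f"P{i + 1:03d}" for i in range(s.n_plants)]
    orths = [f"O{i + 1:02d}" for i in range(s.n_orthopterans)]
    site_cluster = _partition_evenly(sites, s.n_modules)
    species_module = _partition_evenly(plants, s.n_modules)
    orth_pool = list(s.orthopteran_modules) or list(range(1, s.n_modules + 1))
    for i, sp in enumerate(orths):
        species_module[sp] = orth_pool[i % len(orth_pool)]
    species = plants + orths
    guild = {sp: "plant" for sp in plants} | {sp: "orthopteran" for sp in orths}
    cluster_vec = np.array([site_cluster[x] for x in sites])
    module_vec = np.array([species_module[x] for x in species])
    probs = np.where(
        cluster_vec[:, None] == module_vec[None, :], s.p_in, s.p_out
    )
    values = (rng.random(probs.shape) < probs).astype(float)
    m = SiteSpeciesMatrix(
        values=pd.DataFrame(values, index=sites, columns=species),
        guild=guild,
        value_kind="presence",
    )
    return m, species_module, site_cluster


def generate_traits(
    species_module: dict[str, int],
    regimes: dict[int, str],
    seed: int | np.random.Generator,
    trait_names: tuple[str, ...] = PLANT_TRAITS,
    kind: str = "continuous",
    sd_within: float = 0.1,
    divergent_spread: float = 4.0,
) -> TraitTable:
    """Trait table realizing per-module convergence/divergence regimes.

    Continuous traits: convergent modules draw Normal(module mean,
    sd_within) with module means scaled so the global sd stays near 1;
    divergent modules get evenly spaced values (jittered) over
    ``divergent_spread``; neutral modules are iid standard normal. Binary
    traits: module-biased Bernoulli under convergent regimes (p pushed
    toward 0 or 1 per module), fair coin otherwise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = sorted(species_module)
    modules = sorted(set(species_module.values()))
    values = pd.DataFrame(index=species, columns=list(trait_names), dtype=float)
    for trait in trait_names:
        between_sd = max(1.0 - sd_within**2, 0.0) ** 0.5
        for mod in modules:
            members = [sp for sp in species if species_module[sp] == mod]
            regime = regimes.get(mod, "neutral")
            k = len(members)
            if kind == "continuous":
                if regime == "convergent":
                    mean = rng.normal(0.0, between_sd)
                    vals = rng.normal(mean, sd_within, size=k)
                elif regime == "divergent":
                    spaced = np.linspace(
                        -divergent_spread / 2, divergent_spread / 2, k
                    )
                    vals = rng.permutation(spaced) + rng.normal(0, 0.05, size=k)
                else:
                    vals = rng.normal(0.0, 1.0, size=k)
            else:
                if regime == "convergent":
                    p = 0.9 if rng.random() < 0.5 else 0.1
                else:
                    p = 0.5
                vals = (rng.random(k) < p).astype(float)
            values.loc[members, trait] = vals
    return TraitTable(
        values=values, trait_kind={t: kind for t in trait_names}
    )


def _brownian_traits(
    tree: dendropy.Tree, rng: np.random.Generator, rate: float = 1.0
) -> dict[str, float]:
    values: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[node.parent_node]
        step_sd = (rate * max(node.edge.length or 0.0, 0.0)) ** 0.5
        values[node] = parent + rng.normal(0.0, step_sd)
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


def generate_tree_and_conserved_traits(
    n_species: int,
    signal: bool,
    seed: int,
    labels: list[str] | None = None,
    trait_names: tuple[str, ...] = ("conserved_trait",),
) -> tuple[PhyloTree, TraitTable]:
    """Pure-birth ultrametric tree plus traits evolved along it.

    With ``signal`` the traits follow Brownian motion on the branches, so
    trait variance between tips grows with cophenetic distance; without it
    they are iid standard normal (no phylogenetic signal).
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    if labels is None:
        labels = [f"T{i + 1:03d}" for i in range(n_species)]
    tree = _pure_birth_tree(labels, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    values = pd.DataFrame(index=sorted(labels), columns=list(trait_names), dtype=float)
    for trait in trait_names:
        if signal:
            tip_vals = _brownian_traits(tree.tree, rng)
            values[trait] = pd.Series(tip_vals)
        else:
            values[trait] = rng.normal(0.0, 1.0, size=len(labels))
    return tree, TraitTable(values=values, trait_kind={t: "continuous" for t in trait_names})


def _pure_birth_tree(labels: list[str], seed: int) -> PhyloTree:
    """Yule (pure-birth) ultrametric tree over the given tip labels."""
    from dendropy.model import birthdeath

    taxa = dendropy.TaxonNamespace(sorted(labels))
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(labels),
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    # pure-birth trees from the simulator are ultrametric up to float noise
    return PhyloTree(tree)


def generate_environment_and_abundance(
    presence: SiteSpeciesMatrix,
    species_module: dict[str, int],
    site_cluster: dict[str, int],
    driven_modules: dict[str, tuple[int, ...]],
    seed: int | np.random.Generator,
    env_effect: float = 1.0,
    cluster_shift: float = 1.0,
    abundance_mu: float = 0.0,
    abundance_sigma: float = 1.0,
) -> tuple[EnvTables, SiteSpeciesMatrix]:
    """Environmental tables and an abundance matrix wired to them.

    Variables of a driving set get cluster-mean offsets (so the gradient is
    aligned with the planted site clusters) and the log-abundance of species
    in driven modules loads linearly on the first variable of the driving
    set. Abundance zeros coincide exactly with absence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = presence.site_ids
    n = len(sites)
    cluster_vec = np.array([site_cluster[x] for x in sites])
    tables = {}
    var_sets = {"X1": X1_VARS, "X2": X2_VARS, "X3": X3_VARS}
    for set_name, var_names in var_sets.items():
        cols = {}
        driven = driven_modules.get(set_name, ())
        for v in var_names:
            x = rng.normal(0.0, 1.0, size=n)
            if driven:
                offsets = rng.normal(0.0, cluster_shift, size=max(cluster_vec) + 1)
                x = x + offsets[cluster_vec]
            cols[v] = x
        tables[set_name] = pd.DataFrame(cols, index=sites)
    env = EnvTables(tables["X1"], tables["X2"], tables["X3"])

    P = presence.values.to_numpy()
    log_ab = rng.normal(abundance_mu, abundance_sigma, size=P.shape)
    for set_name, driven in driven_modules.items():
        if not driven:
            continue
        driver = tables[set_name].iloc[:, 0].to_numpy()
        driver = (driver - driver.mean()) / max(driver.std(), 1e-12)
        for j, sp in enumerate(presence.species_ids):
            if species_module.get(sp) in driven:
                # species-specific slope: the driver reshuffles the relative
                # composition, not just the total abundance, of the module
                slope = rng.normal(0.0, env_effect)
                log_ab[:, j] = log_ab[:, j] + slope * driver
    abundance = P * np.exp(log_ab)
    ab = SiteSpeciesMatrix(
        values=pd.DataFrame(abundance, index=sites, columns=presence.species_ids),
        guild=dict(presence.guild),
        value_kind="abundance",
    )
    return env, ab


def generate_bundle(s: SyntheticScenario) -> SyntheticBundle:
    """Full reproducible bundle: occurrence, abundance, traits, trees, env.

    All randomness flows from ``s.seed`` through per-component substreams,
    so regeneration from (scenario, seed) is bit-identical.
    """
    ss = np.random.SeedSequence(s.seed)
    sub = ss.spawn(6)
    presence, species_module, site_cluster = generate_occurrence(
        s, np.random.default_rng(sub[0])
    )
    plants = presence.species_of_guild("plant")
    orths = presence.species_of_guild("orthopteran")
    plant_traits = generate_traits(
        {sp: species_module[sp] for sp in plants},
        s.regimes,
        np.random.default_rng(sub[1]),
        trait_names=PLANT_TRAITS,
        kind="continuous",
        sd_within=s.sd_within,
        divergent_spread=s.divergent_spread,
    )
    orth_traits = generate_traits(
        {sp: species_module[sp] for sp in orths},
        s.regimes,
        np.random.default_rng(sub[2]),
        trait_names=ORTHOPTERAN_TRAITS,
        kind="binary",
    )
    tree_seed_p, tree_seed_o = (int(x) for x in ss.generate_state(2) >> 1)
    plant_labels = _tree_tip_order(plants, species_module, s.phylo_signal)
    orth_labels = _tree_tip_order(orths, species_module, s.phylo_signal)
    plant_tree = _pure_birth_tree_ordered(plant_labels, tree_seed_p)
    orth_tree = _pure_birth_tree_ordered(orth_labels, tree_seed_o)
    env, abundance = generate_environment_and_abundance(
        presence,
        species_module,
        site_cluster,
        s.driven_modules,
        np.random.default_rng(sub[3]),
        env_effect=s.env_effect,
        cluster_shift=s.cluster_shift,
        abundance_mu=s.abundance_mu,
        abundance_sigma=s.abundance_sigma,
    )
    return SyntheticBundle(
        scenario=s,
        presence=presence,
        abundance=abundance,
        plant_traits=plant_traits,
        orthopteran_traits=orth_traits,
        plant_tree=plant_tree,
        orthopteran_tree=orth_tree,
        env=env,
        species_module=species_module,
        site_cluster=site_cluster,
    )


def _tree_tip_order(
    species: list[str], species_module: dict[str, int], by_module: bool
) -> list[str]:
    if by_module:
        return sorted(species, key=lambda sp: (species_module[sp], sp))
    return sorted(species)


def _pure_birth_tree_ordered(ordered_labels: list[str], seed: int) -> PhyloTree:
    """Pure-birth tree whose leaves (in traversal order) get the given labels.

    Passing labels ordered by module makes module membership phylogenetically
    clustered; sorted labels give a random (neutral) placement.
    """
    tree = _pure_birth_tree(ordered_labels, seed).tree
    leaves = list(tree.leaf_node_iter())
    for leaf, label in zip(leaves, ordered_labels):
        leaf.taxon.label = label
    return PhyloTree(tree)
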