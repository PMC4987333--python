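"""End-to-end orchestration of the co-occurrence assembly workflow.

Load or generate data -> presence/absence -> exact pairwise classification
-> positive co-occurrence network -> modularity + nestedness with
fixed-marginal nulls (all requested permutation methods side by side) ->
per-species knock-out -> within-module functional/phylogenetic assembly
tests and trait shifts -> Hellinger transform, FDis/PDis dispersion nulls
-> variance partitioning per module and for the whole network. Writes CSV
tables, a GraphML network, and a machine-readable JSON report whose content
is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import dispersion_ses, hellinger, subset_by_module, variance_partition
from .assembly import (
    benjamini_hochberg,
    module_distance_ses,
    module_ses_frame,
    trait_shift_frame,
    trait_shift_tests,
)
from .cooccur import build_network, classify_pairs, pairs_to_frame, retained_species_report
from .datatypes import (
    EnvTables,
    SiteSpeciesMatrix,
    TraitTable,
    braun_blanquet_to_cover,
    read_env_tables,
    read_site_species,
    read_traits,
    to_presence,
)
from .distances import functional_distance
from .nulls import (
    knockout_importance,
    knockout_importance_from_data,
    structure_ses,
    structure_ses_matrix_null,
)
from .phylo import cophenetic_distances, read_newick
from .structure import greedy_modules, nestedness
from .synthetic import SyntheticScenario, generate_bundle

log = logging.getLogger("coocnet")

GUILD_NAMES = ("plant", "orthopteran")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults match the headline analysis."""

    # data: either a synthetic scenario, or explicit input paths
    scenario: dict | None = None
    inputs: dict | None = None  # keys: site_species, value_kind, guilds, traits_*, tree_*, env_x*
    alpha: float = 0.05
    min_expected: float = 1.0
    methods: tuple[str, ...] = ("swap", "tswap", "quasiswap")
    n_perm_structure: int = 9999
    n_perm_assembly: int = 9999
    n_perm_dispersion: int = 9999
    n_perm_varpart: int = 999
    seed: int = 0
    out_dir: str = "coocnet_run"
    # alternative modes
    matrix_null: bool = False  # permute site × species matrix instead of adjacency
    knockout_from_data: bool = False
    matrix_null_n_perm: int = 199

    def __post_init__(self) -> None:
        for name in ("n_perm_structure", "n_perm_assembly", "n_perm_dispersion", "n_perm_varpart"):
            if getattr(self, name) < 99:
                raise ValueError(f"{name} must be >= 99 for a reportable p-value")
        if self.scenario is None and self.inputs is None:
            raise ValueError("config needs either a synthetic scenario or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


@dataclass
class LoadedData:
    presence: SiteSpeciesMatrix
    abundance: SiteSpeciesMatrix | None
    traits: dict[str, TraitTable]
    phylo_dist: dict[str, "object"]
    env: EnvTables | None


def _load(config: RunConfig) -> LoadedData:
    if config.scenario is not None:
        scenario = SyntheticScenario(**config.scenario)
        bundle = generate_bundle(scenario)
        return LoadedData(
            presence=bundle.presence,
            abundance=bundle.abundance,
            traits={"plant": bundle.plant_traits, "orthopteran": bundle.orthopteran_traits},
            phylo_dist={
                "plant": cophenetic_distances(bundle.plant_tree),
                "orthopteran": cophenetic_distances(bundle.orthopteran_tree),
            },
            env=bundle.env,
        )
    paths = config.inputs
    value_kind = paths.get("value_kind", "presence")
    m = read_site_species(paths["site_species"], value_kind, paths["guilds"])
    abundance = None
    if value_kind == "braun_blanquet":
        abundance = braun_blanquet_to_cover(m)
    elif value_kind == "abundance":
        abundance = m
    traits, phylo = {}, {}
    for g in GUILD_NAMES:
        if f"traits_{g}" in paths:
            kinds = paths.get(f"trait_kinds_{g}", {})
            traits[g] = read_traits(paths[f"traits_{g}"], kinds)
        if f"tree_{g}" in paths:
            phylo[g] = cophenetic_distances(read_newick(paths[f"tree_{g}"]))
    env = None
    if all(f"env_{k}" in paths for k in ("x1", "x2", "x3")):
        env = read_env_tables(paths["env_x1"], paths["env_x2"], paths["env_x3"])
    return LoadedData(
        presence=to_presence(m) if value_kind != "presence" else m,
        abundance=abundance,
        traits=traits,
        phylo_dist=phylo,
        env=env,
    )


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all outputs under ``out_dir``.

    Returns the run report (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] >> 1)
        for name, s in zip(
            ("structure", "assembly", "dispersion", "varpart"), ss.spawn(4)
        )
    }
    report["stage_seeds"] = stage_seed

    t = _stage("load")
    data = _load(config)
    presence = to_presence(data.presence)
    report["stages"]["load"] = {
        "n_sites": len(presence.site_ids),
        "n_species": len(presence.species_ids),
        "elapsed_s": round(time.perf_counter() - t, 3),
    }

    t = _stage("cooccurrence")
    pairs = classify_pairs(presence, alpha=config.alpha, min_expected=config.min_expected)
    pairs_to_frame(pairs).to_csv(out / "pair_cooccurrence.csv", index=False)
    net = build_network(pairs, presence.guild)
    nx.write_graphml(net, out / "network.graphml")
    pd.DataFrame(sorted(net.edges), columns=["species_a", "species_b"]).to_csv(
        out / "edges.csv", index=False
    )
    retained = retained_species_report(pairs, presence.guild)
    report["stages"]["cooccurrence"] = {
        "alpha": config.alpha,
        "min_expected": config.min_expected,
        "n_pairs": len(pairs),
        "n_positive": sum(p.classification == "positive" for p in pairs),
        "n_negative": sum(p.classification == "negative" for p in pairs),
        "n_untestable": sum(p.classification == "untestable" for p in pairs),
        "retained": retained,
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "elapsed_s": round(time.perf_counter() - t, 3),
    }

    t = _stage("structure")
    partition = greedy_modules(net)
    pd.DataFrame(
        sorted(partition.membership.items()), columns=["species", "module"]
    ).to_csv(out / "modules.csv", index=False)
    nest_obs = nestedness(net)
    struct: dict = {
        "q": partition.q,
        "n_modules": partition.n_modules,
        "nestedness": nest_obs,
        "ses": {},
    }
    for method in config.methods:
        struct["ses"][method] = {}
        for stat in ("modularity", "nestedness"):
            res = structure_ses(
                net,
                statistic=stat,
                n_perm=config.n_perm_structure,
                method=method,
                seed=stage_seed["structure"],
            )
            struct["ses"][method][stat] = res.to_dict()
    if config.matrix_null:
        struct["ses"]["matrix-tswap"] = {}
        for stat in ("modularity", "nestedness"):
            res = structure_ses_matrix_null(
                presence,
                statistic=stat,
                n_perm=config.matrix_null_n_perm,
                seed=stage_seed["structure"],
                alpha=config.alpha,
                min_expected=config.min_expected,
            )
            struct["ses"]["matrix-tswap"][stat] = res.to_dict()
    struct["elapsed_s"] = round(time.perf_counter() - t, 3)
    report["stages"]["structure"] = struct

    t = _stage("knockout")
    if config.knockout_from_data:
        ko = knockout_importance_from_data(
            presence, alpha=config.alpha, min_expected=config.min_expected
        )
    else:
        ko = knockout_importance(net, partition)
    ko.to_csv(out / "knockout.csv")
    report["stages"]["knockout"] = {
        "mode": "data" if config.knockout_from_data else "network",
        "n_species": int(len(ko)),
        "elapsed_s": round(time.perf_counter() - t, 3),
    }

    t = _stage("assembly")
    assembly_frames = []
    shift_frames = []
    for g in GUILD_NAMES:
        guild_species = [s for s in net.nodes if presence.guild.get(s) == g]
        if len(guild_species) < 2:
            continue
        dists = {}
        if g in data.traits:
            tr = data.traits[g]
            dists["functional_multi"] = functional_distance(tr)
            for trait in tr.trait_names:
                dists[f"functional_{trait}"] = functional_distance(tr, [trait])
        if g in data.phylo_dist:
            dists["phylogenetic"] = data.phylo_dist[g]
        for kind, dmat in dists.items():
            usable = [s for s in guild_species if s in dmat.species_ids]
            res = module_distance_ses(
                partition,
                dmat,
                usable,
                n_perm=config.n_perm_assembly,
                seed=stage_seed["assembly"],
                distance_kind=kind,
                guild=g,
            )
            assembly_frames.append(module_ses_frame(res))
        if g in data.traits:
            shifts = trait_shift_tests(data.traits[g], partition, guild_species)
            df = trait_shift_frame(shifts)
            df.insert(0, "guild", g)
            shift_frames.append(df)
    if assembly_frames:
        adf = pd.concat(assembly_frames, ignore_index=True)
        ok = adf["p"].notna()
        adf["p_bh"] = np.nan
        if ok.any():
            adf.loc[ok, "p_bh"] = benjamini_hochberg(adf.loc[ok, "p"].to_numpy())
        adf.to_csv(out / "module_assembly.csv", index=False)
    if shift_frames:
        pd.concat(shift_frames, ignore_index=True).to_csv(
            out / "trait_shifts.csv", index=False
        )
    report["stages"]["assembly"] = {
        "n_perm": config.n_perm_assembly,
        "seed": stage_seed["assembly"],
        "n_tests": sum(len(f) for f in assembly_frames),
        "elapsed_s": round(time.perf_counter() - t, 3),
    }

    abundance = data.abundance
    if abundance is not None:
        t = _stage("dispersion")
        disp_rows = []
        for g in GUILD_NAMES:
            guild_species = abundance.species_of_guild(g)
            if len(guild_species) < 3:
                continue
            sub = abundance.subset_species(guild_species)
            dmats = {}
            if g in data.traits:
                dmats["functional"] = functional_distance(data.traits[g])
            if g in data.phylo_dist:
                dmats["phylogenetic"] = data.phylo_dist[g]
            for kind, dmat in dmats.items():
                common = [s for s in guild_species if s in dmat.species_ids]
                res = dispersion_ses(
                    sub.subset_species(common),
                    dmat.subset(common),
                    n_perm=config.n_perm_dispersion,
                    seed=stage_seed["dispersion"],
                    guild=g,
                )
                disp_rows.append(
                    {
                        "guild": g,
                        "distance_kind": kind,
                        "index": res.index_name,
                        "mean": res.mean,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "ses": res.ses,
                        "p": res.p,
                        "n_perm": res.n_perm,
                        "seed": res.seed,
                    }
                )
        if disp_rows:
            pd.DataFrame(disp_rows).to_csv(out / "dispersion.csv", index=False)
        report["stages"]["dispersion"] = {
            "n_tests": len(disp_rows),
            "elapsed_s": round(time.perf_counter() - t, 3),
        }

        if data.env is not None:
            t = _stage("varpart")
            network_species = sorted(net.nodes)
            ab_net = abundance.subset_species(
                [s for s in network_species if s in abundance.species_ids]
            )
            responses = {"whole network": ab_net}
            for module, mat in subset_by_module(ab_net, partition).items():
                responses[f"module {module}"] = mat
            vp_frames = []
            skipped = []
            for label, mat in responses.items():
                h = hellinger(mat)
                sites = list(h.values.index)
                try:
                    vp = variance_partition(
                        h.values,
                        data.env.x1.loc[sites],
                        data.env.x2.loc[sites],
                        data.env.x3.loc[sites],
                        n_perm=config.n_perm_varpart,
                        seed=stage_seed["varpart"],
                        response_label=label,
                    )
                except Exception as exc:  # e.g. too few occupied sites
                    log.warning("varpart skipped for %s: %s", label, exc)
                    skipped.append(label)
                    continue
                vp_frames.append(vp.to_frame())
            if vp_frames:
                pd.concat(vp_frames, ignore_index=True).to_csv(
                    out / "varpart.csv", index=False
                )
            report["stages"]["varpart"] = {
                "n_responses": len(responses),
                "skipped": skipped,
                "n_perm": config.n_perm_varpart,
                "seed": stage_seed["varpart"],
                "elapsed_s": round(time.perf_counter() - t, 3),
            }

    # elapsed times vary between runs; the deterministic report omits them
    det = json.loads(json.dumps(report))
    for stage in det["stages"].values():
        stage.pop("elapsed_s", None)
    (out / "report.json").write_text(json.dumps(det, indent=2, sort_keys=True) + "\n")
    return report
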