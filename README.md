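# coocnet

Multi-rule community-assembly analysis of species co-occurrence networks.

Ecologists studying how communities assemble — through biotic interactions,
environmental filtering, or neutral drift — increasingly read those
processes off the structure of co-occurrence networks. `coocnet` implements
the full analysis chain for a two-guild system (vascular plants and
orthopterans surveyed across permanent grasslands) as a tested, reusable
Python pipeline:

1. **Pairwise co-occurrence classification.** For species occupying
   N₁ and N₂ of N sites, the number of jointly occupied sites under random
   placement is exactly hypergeometric,
   P(J = j) = C(N₁, j)·C(N − N₁, N₂ − j) / C(N, N₂).
   A pair is *positive* when P(J ≥ j_obs) < α, *negative* when
   P(J ≤ j_obs) < α (α = 0.05; pairs with expected joint count N₁N₂/N < 1
   are untestable). Positive pairs become the edges of an undirected
   network; species with no positive partner are filtered out.
2. **Network structure.** Modularity Q = Σ_c (e_cc − a_c²) (Newman), with
   modules found by fast-greedy agglomeration, and NODF nestedness rescaled
   to [0, 1]. Both are tested against fixed-marginal (degree-preserving)
   nulls — sequential checkerboard `swap`, trial-swap `tswap`, and the
   independent-fill `quasiswap` — reporting SES = (obs − null mean)/null sd
   and lower-tail permutation p-values.
3. **Species importance.** A knock-out analysis removes each species in
   turn, recomputes Q and nestedness, and standardizes the deltas:
   SES_i = (Δ_i − mean Δ)/sd Δ. Species with negative modularity SES make
   the network *more* modular when removed (connectors); positive SES marks
   module hubs.
4. **Assembly rules inside modules.** Mean within-module functional (Gower,
   mixed continuous/binary traits) and phylogenetic (cophenetic) distances
   against a null that reassigns species to modules holding module sizes
   fixed: low lower-tail p ⇒ trait convergence (filtering), high p ⇒
   divergence (limiting similarity). Trait shifts across modules via
   Kruskal–Wallis (continuous) and exact contingency tests (binary).
5. **Abundance-based counterparts.** Functional/phylogenetic dispersion
   (FDis/PDis: abundance-weighted mean distance to the community centroid
   in principal-coordinate space) against a species-identity permutation
   null, and RDA variance partitioning of Hellinger-transformed abundances
   over three explanatory sets — agricultural practices (X1), soil (X2),
   spatial position (X3) — with adjusted-R² fractions by
   inclusion–exclusion and Freedman–Lane tests of the pure fractions,
   per module and for the whole network.

Because the original field data are not deposited, the package ships a
first-class synthetic-data generator that emulates the study design
(48 sites, ~200 plants, ~20 orthopterans, five planted modules,
per-module trait regimes, Brownian traits on pure-birth phylogenies,
module-wired environmental drivers) so every stage can be validated
against known ground truth.

## Worked example

Score the default synthetic scenario's network structure from the shell:

```
$ coocnet structure --seed 3 --n-perm 999
Q=0.7845 modules=5 nestedness=0.1689
modularity: obs=0.7845 SES=183.30 p=1.0000 (quasiswap)
nestedness: obs=0.1689 SES=-6.94 p=0.0010 (quasiswap)
```

The five planted modules are recovered with very high modularity
(Q = 0.78 ≫ 0.3, the conventional threshold for strong structuring); the
lower-tail p of 1.0 says every null draw fell below the observed Q
(the network is far more modular than its degree sequence implies), while
nestedness sits significantly *below* its null (SES = −6.9, p = 0.001):
a modular, anti-nested network, as planted.

The full workflow — co-occurrence table, GraphML network, module map,
knock-out table, assembly tests, dispersion and variance partitioning,
plus a machine-readable JSON report — runs with:

```
$ coocnet run --seed 3 --n-perm 99 --out demo
network: 218 species, 3152 edges; Q=0.784 (5 modules), nestedness=0.169
outputs in demo
```

The same library surface is importable (`coocnet.classify_pairs`,
`coocnet.greedy_modules`, `coocnet.structure_ses`,
`coocnet.module_distance_ses`, `coocnet.variance_partition`, …); see
`docs/methods.md` for the statistical details and design choices.

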