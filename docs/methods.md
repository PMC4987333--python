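# Methods

This note records the statistical models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic test bed does and
does not establish about real data.

## Pairwise co-occurrence model

The classification of species pairs uses the exact probabilistic model of
pairwise co-occurrence: conditional on the two species' occupancy counts
N₁ and N₂ over N sites, the joint count J is hypergeometric. `pair_pmf`
evaluates the law in log-space (log-gamma binomials), so site counts in the
hundreds cause no overflow; the test suite verifies it against brute-force
enumeration of all placements (N ≤ 8) and against an independent
hypergeometric implementation up to N = 200.

Conventions, all configurable:

- **α = 0.05** per tail. The source model's convention; the tails share the
  probability atom at the observed count, i.e. p_lt = P(J ≤ j_obs) and
  p_gt = P(J ≥ j_obs), so p_lt + p_gt ≥ 1 and both tails can never be
  simultaneously significant.
- **Testability: expected joint count N₁N₂/N ≥ 1** (`min_expected`,
  0 disables). Untestable pairs are reported but never become edges.
- Between-guild pairs are scored identically to within-guild pairs: the
  analysis network deliberately mixes plants and orthopterans.
- Negative co-occurrences are tabulated but not used for the graph; the
  analysis network is the *positive* co-occurrence network, and species
  with no positive partner are removed before any structure statistic.

## Modularity and nestedness

`newman_q` implements Q = Σ_c (e_cc − a_c²) directly from edge fractions.
Module detection is the fast-greedy agglomerative maximization of Q,
delegated to igraph's C implementation for speed (the knock-out and the
permutation nulls run it ~10⁵ times per analysis); it is deterministic, and
module ids are canonicalized (1..k, ordered by size then smallest member
label) so runs are reproducible without a seed. On a fixed set of small
graphs the detected partition attains the optimum found by exhaustive
search over all set partitions; like any greedy heuristic it is not
guaranteed optimal on arbitrary graphs.

Nestedness is the NODF family index on the binary adjacency: for every row
pair (and column pair) with strictly decreasing marginal totals, the paired
overlap is the fraction of the sparser neighbourhood contained in the
denser one; ties in degree contribute zero (the decreasing-fill rule). The
score is rescaled from 0–100 to [0, 1]. Note that a simple-graph adjacency
can never reach exactly 1: some pair of vertices always shares a degree,
and tied pairs score zero. The value-1 extreme is attainable (and tested)
on general binary matrices with distinct fills.

## Fixed-marginal nulls

The null ensemble randomizes the network while fixing every species'
degree (row and column sums of the symmetric adjacency):

- **swap** — sequential 2×2 checkerboard swaps (double edge swaps) on the
  upper triangle with symmetric mirroring; a chain step is a *successful*
  swap.
- **tswap** — trial swaps: a step is an *attempted* swap whether or not it
  can be applied. This removes the classic bias of the plain swap chain.
  One concrete manifestation, documented in the tests: on the 2-regular
  5-vertex state space (12 labeled cycles) a fixed even number of
  successful swaps can never leave the parity class of the starting graph,
  so `swap` samples exactly half the states; `tswap` and `quasiswap` are
  uniform there (chi-square at α = 0.01 over 10⁴ draws).
- **quasiswap** — an independent fill: uniform random stub pairing with the
  exact degree sequence (an intermediate multigraph), then repaired back to
  a simple graph by checkerboard swaps that never increase the number of
  self-loops or duplicate edges. Draws are independent of the observed
  adjacency.

Chain defaults: burn-in 10·|E| steps, thinning 5·|E| steps between samples
— conventional mixing allowances for checkerboard chains. Graphs with no
swappable checkerboard (e.g. complete graphs) are returned unchanged with a
warning. All three methods are reported side by side by the pipeline and
never silently mixed.

SES = (observed − null mean)/null sd with the sample (n−1) standard
deviation; p is the lower-tail quantile (1 + #{null < obs})/(1 + n_perm),
so convergence-type departures give small p and divergence-type departures
give p near 1, and two one-sided readings at α = 0.05 each apply. Default
n_perm is 9,999 (reducible everywhere; the pipeline refuses n_perm < 99
for any reported p). A zero-spread null leaves SES undefined (reported as
such, never coerced to 0).

An alternative null that permutes the site × species matrix itself (fixed
row/column sums, trial checkerboard swaps) and rebuilds the network per
draw is available behind the `matrix_null` flag for sensitivity analysis;
it is far slower since the whole pairwise classification is redone per
draw, and empty null networks contribute 0 (no structure).

## Knock-out importance

Each species is removed from the *network* (the default; a
`knockout_from_data` flag instead removes it from the presence matrix and
re-runs classification), module detection is re-run, and
Δ_i = initial − leave-one-out for both Q and nestedness.
SES_i = (Δ_i − mean Δ)/sd Δ with the sample sd (switchable to population
sd). Removals that leave an edgeless network are flagged NaN and excluded
from standardization; an all-equal Δ vector (vertex-transitive graphs)
leaves every SES undefined rather than zero. The SES columns have mean 0
by construction whenever defined.

## Module assembly tests

Within-module mean pairwise distance (per guild) is compared against a
null that *jointly* reassigns the guild's species to modules, holding all
module sizes fixed and the distance matrix intact — the reassignment
preserves the distance structure exactly, and the multiset of module sizes
in every draw. Modules with fewer than two guild species are reported
not-testable (in practice this restricts orthopteran tests to the two or
three modules that hold several orthopterans). Functional distances are
Gower with range-normalized continuous traits and simple-matching binary
traits, pairwise-complete over missing values; no distance metric is
canonical for mixed traits, and Gower is the de facto standard. Raw
p-values are reported without multiplicity correction (a Benjamini–
Hochberg column is emitted for reference but not used for flags).

Trait shifts across modules: Kruskal–Wallis for continuous traits; for
binary traits an exact conditional test on the module × value contingency
table by full enumeration of tables with the observed margins (feasible at
these guild sizes; verified against an independent 2×2 implementation).

## Abundance analyses

FDis/PDis: principal coordinates of the (functional or cophenetic)
distance matrix, retaining negative-eigenvalue axes as imaginary
coordinates whose squared contributions are subtracted (floored at zero)
when measuring distances — the standard correction for semi-Euclidean
distance matrices. Per site, the index is the abundance-weighted mean
distance of present species to the abundance-weighted centroid; sites with
fewer than two species score 0. The whole-dataset statistic is the
unweighted mean over sites (a site-weighted variant is a one-line change);
the null permutes species identities (whole abundance columns reassigned
to species labels, within guild), preserving local abundance and diversity
exactly. PDis is FDis computed on the cophenetic matrix.

Variance partitioning: Hellinger-transformed abundances (√ of within-site
relative abundance; zero-total sites dropped with a warning) regressed on
the three explanatory sets. R² is the multivariate redundancy statistic
(explained sum of squares over total; canonical axes are never needed and
not computed), adjusted by Ezekiel's formula. The seven fractions follow
by inclusion–exclusion over the seven models and sum to the full-model
adjusted R² exactly (asserted to 1e−10); joint fractions may be negative
and are reported as computed. Pure fractions are tested by Freedman–Lane
residual permutation under the reduced model with the partial pseudo-F as
the statistic — the raw semipartial R² is not pivotal and is measurably
anticonservative, while the pseudo-F test is calibrated at the nominal
level in the suite's independence check. Collinear predictor columns are
dropped with a warning (QR with pivoting).

## Synthetic data

The generator mirrors the target study's scale: 48 sites, 197 plants,
22 orthopterans, 5 modules. Sites belong to clusters matched 1:1 with
modules; species of module k occur at cluster-k sites with p_in = 0.7 and
elsewhere with p_out = 0.05 (independent Bernoulli draws). Orthopterans
are concentrated in modules 1, 2 and 4; plants are spread evenly. Traits
follow per-module regimes — convergent (Normal with within-module sd 0.1
around a module mean, global sd ≈ 1), divergent (evenly spaced, jittered),
neutral (iid standard normal); binary traits get module-biased Bernoulli
probabilities under convergence. Default regimes plant one convergent and
two divergent plant modules with the rest neutral. Phylogenies are
pure-birth (Yule) ultrametric trees; the `phylo_signal` flag clusters tips
by module (giving phylogenetic structure) or assigns them neutrally (the
default, matching a system where phylogeny is largely decoupled from
module membership). Brownian trait evolution along branches is available
for conserved-trait experiments.

Abundance is presence × LogNormal(0, 1), with per-species log-abundance
slopes ~ Normal(0, env_effect = 2) on the first variable of each driving
environmental set. The slopes must be species-specific: a module-constant
loading cancels in within-module relative (Hellinger) composition and is
undetectable by construction. Variables of driving sets also receive
cluster-mean offsets (cluster_shift = 1) so that, by default, the spatial
set aligns with the planted site clusters — spatial structure drives
everything, as in real landscapes. By default the practices set (X1)
drives modules 2, 4 and 5 and the spatial set (X3) drives all modules.

The *driver-recovery experiment* in the acceptance suite uses a variant
scenario (p_out = 0.2, cluster_shift = 0, X1 driving module 2 only): with
the default sparse occupancy the driven module exists at only ~10 of 48
sites, so no abundance-composition signal can span the practice gradient;
and with cluster-aligned offsets every module's composition is genuinely
(not spuriously) correlated with X1 through occupancy. The variant isolates
the abundance pathway the experiment is about.

All randomness flows from a single seed through per-component substreams;
bundle regeneration from (scenario, seed) is bit-identical. Ground-truth
labels are carried alongside the data and never consumed by the analysis
functions, which accept only the plain data containers.

### What the synthetic bed does not show

The generator omits observation error (Braun-Blanquet discretization is
supported as input but not simulated), spatial autocorrelation beyond the
cluster structure, species-abundance distributions with realistic
dominance, and any feedback between guilds. Passing tests demonstrate that
the pipeline recovers structure it is designed to detect under its own
assumptions — not that those assumptions hold in any particular field
system.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep the default suite
fast while leaving thresholds untouched: module-recovery ARI over 100
generator seeds; modularity SES (n_perm = 999) over 20 seeds;
planted-convergence power over 100 seeds (n_perm = 999) and neutral
calibration over 200 seeds (n_perm = 199); driver recovery over 50 seeds
(n_perm = 199); null-sampler uniformity over 10⁴ draws. The acceptance
script uses n_perm = 999 throughout on the full default scenario.

## Known limitations

- The fast-greedy optimizer inherits the resolution limit of modularity
  maximization; very small modules attached to large ones may be merged.
- `quasiswap`'s repair phase is a stochastic reduction; its output
  distribution is exactly uniform on symmetric state spaces and observed
  to be uniform on the enumerable test cases, but no exact-uniformity
  proof is claimed for arbitrary degree sequences.
- Fisher's exact test by enumeration is exponential in table size; it is
  intended for the small module × trait tables that arise here (tens of
  observations), not for large tables.
- The Braun-Blanquet midpoint table is the conventional phytosociological
  one; surveys using a different degree convention should override it via
  the `scale` argument.
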