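# Methods

This note documents the models and procedures implemented in `antweb`, the
choices made where the methodology is genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

The atomic record is an interaction event: one observation of an ant
species on a plant species, classified by resource
(`EFN | flower | fruit | trophobiont | visit`), with site, plot, season and
a worker count. Interaction weight is the number of *events*, never the
number of workers; worker counts are recruitment metadata only. A layer
matrix pools events of one resource type over the requested sites, drops
species with all-zero margins, and orders species lexicographically so
that every downstream stochastic procedure is reproducible from its seed.
The multilayer (pooled) matrix is the element-wise sum of all five layers
— including bare visits — on the union of species, so its total equals the
event count exactly. Events are pooled across sites *before* species are
dropped; per-site matrices are built only for the descriptor and core
analyses.

Trophobiont-mediated interactions are collapsed to plant × ant: the
package takes the ant–plant perspective throughout and does not resolve
trophobiont species.

## Network metrics

**Complementary specialization H2′.** The two-dimensional Shannon entropy
H2 of the cell proportions is rescaled between the minimum and maximum
entropies attainable by non-negative integer matrices with the observed
margins: H2′ = (H2max − H2)/(H2max − H2min), 0 when the bounds coincide.
For totals ≤ 12 the bounds are exact (exhaustive enumeration of all
margin-constrained matrices); above that they come from heuristic fills —
a greedy largest-to-largest allocation for the minimum, and a
largest-remainder integer rounding of the independence expectation
r_i c_j/F with exact margin repair for the maximum. On pathological
margins the heuristic bounds can be slightly interior to the exact ones;
the reported value is clamped to [0, 1]. Two edge cases worth knowing:
(i) degenerate margins whose tables all tie in entropy give H2′ = 0 by
convention; (ii) because the bounds are integer fills, H2′ is only
*asymptotically* scale-invariant — multiplying a tiny matrix by a constant
refines the attainable extremes and can genuinely move the index (the test
suite asserts invariance between two large scalings of the same
proportions, not between tiny and large).

**Weighted nestedness WNODF.** Rows and columns are sorted independently
by decreasing totals (stable sort; ties keep label order and contribute
zero under the decreasing-fill rule). A row pair contributes
100 · #{k : 0 < a_jk < a_ik} / #{k : a_jk > 0} when the upper row's total
strictly exceeds the lower's; column pairs symmetrically; the index is the
mean over all row and column pairs.

**Morisita-Horn niche overlap.** C = 2 Σ p_i q_i/(Σ p_i² + Σ q_i²) on
relative-use vectors, averaged (unweighted) over all pairs of one guild
(ants by default: matrix columns). This is the classic Morisita-Horn
formula, not the entropy-based Horn variant; the choice is recorded in the
metric's metadata.

**Degree centrality** is the binary link count per species — weights are
deliberately ignored.

## Modularity

Barber's weighted bipartite modularity
Q = Σ_ij [a_ij/F − r_i c_j/F²] δ(m_i, m_j) is maximized by simulated
annealing over partitions of the joint species set. Schedule and moves:
initial temperature T0 = 0.02·F, geometric cooling ×0.99 per sweep of S
proposals (S = species count), move mix of 85% single-species
reassignments (to an occupied or fresh module), 10% module merges, 5%
random bipartition splits, Metropolis acceptance, stop after 50·S
proposals without improving the best Q. The best state then gets a greedy
best-single-move refinement to its local optimum, and the result is never
worse than the single-module partition (Q = 0). The annealing kernel is
numba-compiled because null standardization refits modularity on hundreds
of randomized matrices (~7 ms per fit at 78 × 30 after one-time
compilation).

`best_of` repeats the fit with restart seeds spawned deterministically
from a master seed and keeps the best Q — the "retain the optimum over
1,000 iterations" practice; "iterations" is read as restarts. Observed Q
uses many restarts; each null matrix gets one fit (the standard practical
compromise; configurable).

**Standardized Q** = (Q_obs − mean Q_null)/sd Q_null over Patefield draws,
significant at ≥ 2 (one-sided). Note that an *exactly uniform* matrix
scores far *below* its null (z ≈ −4.5 at 5 × 5, total 100): random tables
with fixed margins always contain incidental modularity (~0.1), so the
null-typical object is a random draw (|z| ≲ 1), not the uniform table.
The one-sided rule is what both fail.

## Null models and Monte-Carlo tests

All significance is conditional on the observed margins via the Patefield
algorithm (uniform over the multiple-hypergeometric distribution),
delegated to `scipy.stats.random_table(..., method="patefield")`; 1-row or
1-column tables are forced by their margins and short-circuited (scipy's
Patefield path misbehaves there). P-values use the add-one convention
p = (1 + x)/(N + 1), never exactly zero; two-sided p-values are the
doubled smaller tail, capped at 1. Default sidedness: greater for H2′ and
WNODF (specialization/nestedness excess), two-sided for Horn and for layer
comparisons.

The pairwise layer test randomizes *each layer with its own Patefield
null* and differences the metric: the null hypothesis is that the observed
structural difference is what margin effects alone produce. The underlying
study leaves the resampling unit unstated; a site-level permutation is an
alternative reading that is not implemented. Fruit is excluded from
comparisons by default (too small for size-sensitive metrics);
overridable. Type-I error of the test is calibrated in the acceptance
suite: rejection rate at α = 0.05 over 500 null pairs falls in
[0.02, 0.09].

## Cores, PERMANOVA, NMDS

Within each (site, resource) network the core is every species whose
binary degree strictly exceeds the mean degree over all nodes pooled
across guilds (a per-guild threshold is available behind a flag). Core
composition per guild becomes a presence/absence incidence over
(site, resource) rows; rows with empty cores are dropped with a logged
count. Distances are Jaccard by default (Bray-Curtis optional); the
resource effect is tested by one-way PERMANOVA (Anderson's partitioning of
squared distances, pseudo-F, R² = SS_between/SS_total) with free row
permutation, exhaustively enumerated for small designs. Beware the
granularity of small designs: two groups of three rows cannot reach
p < 0.1 under free permutation. NMDS is nonmetric SMACOF
(scikit-learn, ties averaged in the monotone regression) over
multiple random starts, reporting Kruskal stress-1 and centered
coordinates.

Site-level descriptors (size = interacting species, richness = distinct
pairs, frequency = events) are compared across resource types by log-link
Poisson GLMs (statsmodels IRLS); the reported statistic is the deviance
difference against the intercept-only model on a χ² with (levels − 1) df.

## Synthetic data generator

The generator emulates the *shape* of a year of multi-site observation
sampling: ~795 events over 7 sites, 78 plant and 30 ant species, layer mix
66% visit / 20% EFN / 8% flower / 5% trophobiont / 1% fruit, log-normal
species weights (σ = 1.5) giving a few strongly dominant ants, and a fruit
layer restricted to 4 ant species. Mechanism: each species has a weight
and a latent trait in [0, 1]; pair propensity in a layer is
weight × weight × exp(−(s·m_layer)²·d²) with trait distance d, global
specialization knob s and per-layer multipliers
(visit 1 < EFN 2.5 < fruit 3 < flower 4 < trophobiont 6, mirroring the
observed specialization ordering), optionally × a module bonus and core
boosts. Events are one multinomial draw over (site, layer, plant, ant)
cells — total events conserved exactly, identical seeds give identical
tables. Each (site, layer) block is normalized before the multinomial so
the realized layer mix matches the configuration regardless of how much
mass the matching kernel removes.

Planted core structure: the heaviest `core_ants_shared = 4` ants are
boosted ×10 in every layer and given central traits (dominant,
massively recruiting ants are trait generalists — they stay central under
any kernel width); each feeding layer gets a disjoint set of 5 boosted
(×14), trait-typical, widespread plants. Ant traits receive a per-site
Gaussian displacement (σ = 0.2), representing site-level turnover in ant
activity; without it the same secondary ants enter a layer's core at every
site and the ant-core PERMANOVA sees spurious layer signal. Under these
defaults the pipeline reproduces the qualitative core contrast — ant-core
PERMANOVA p > 0.05 and plant-core p ≤ 0.05 — in ≥ 80% of replicates, and
the top five ants carry > 50% of events in nearly all replicates.

Two recovery experiments isolate single knobs: the specialization
monotonicity check (H2′ of EFN layers vs. s, Spearman ρ > 0.9) and the
s → ∞ limit (every plant converges to one partner; pooled H2′ → 1) are
run with core boosts, site jitter and the fruit restriction disabled,
because planted core dominance deliberately caps how specialized the
dominant block can become and would confound the single-knob experiment.

What the generator does **not** emulate: seasonal phenology (the season
field is structureless), trophobiont species identity, mechanistic
foraging or spatial autocorrelation between plots, and abundance-driven
sampling effort differences between sites. Passing recovery tests
therefore demonstrate that the pipeline detects these *kinds* of structure
at field-realistic sample sizes — not that any particular field system
contains them.

## Problem sizes and numerical choices

Defaults aimed at production runs: 999 metric nulls, 1000 modularity
nulls, 1000 observed restarts, 999 permutations. The test suite and the
acceptance script scale these down (tens to low hundreds of nulls,
best-of-10 to 50) — at matrix sizes of 78 × 30 this keeps each full
pipeline run in seconds while leaving every Monte-Carlo estimate's
precision matched to what its assertions need. Degenerate inputs surface
as typed signals rather than numbers: empty layers, metrics on 1 × n
matrices, zero-variance null distributions, all-zero distance matrices and
all-empty core designs each raise a dedicated exception. Margin-sort ties
in WNODF keep original label order and contribute zero; module labels are
canonicalized by first appearance so partitions compare equal across runs.

## Known limitations

- Heuristic H2′ bounds above total 12 are near-optimal, not certified;
  exact bounds are exponential and only used for small totals.
- The annealing optimum is a local one; best-of-N restarts make global
  misses rare at the sizes tested (exhaustive search verifies 4 × 4
  fixtures) but give no guarantee at field scale.
- PERMANOVA assumes exchangeability of (site, resource) rows under the
  null; the site pairing across layers is ignored (as in the standard
  one-way design).
- The layer-difference test conditions on margins; it cannot detect
  differences that live entirely in the margins themselves.
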