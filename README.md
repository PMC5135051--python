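# antweb

Multilayer ant–plant interaction network analysis.

Foliage-dwelling ants exploit several plant-derived food rewards at once —
extrafloral nectar (EFN), floral nectar and pollen, fruit pulp, and the
honeydew of trophobiont hemipterans — and most visits to plants involve no
feeding at all. Treating each resource type as one weighted bipartite layer
(plants × ants, cells = interaction-event counts) and the pooled matrix as
the multilayer network, `antweb` asks the two questions such studies turn
on:

1. **Do resource types differ in network structure?** Per layer it computes
   complementary specialization H2′, weighted nestedness WNODF, mean
   Morisita-Horn niche overlap among ants, and QuanBiMo-style modularity Q
   (simulated annealing, best of N restarts), with significance from the
   Patefield fixed-margin null model; layers are compared pairwise by a
   Monte-Carlo test on metric differences, and site-level descriptors
   (size, richness, frequency) by Poisson GLMs.
2. **Is the core of central species shared across layers?** Within each
   site and layer, species with degree above the network mean form the
   core; core composition is compared across resource types by PERMANOVA
   on Jaccard distances and ordered by NMDS.

Because field matrices of this kind are rarely deposited, the package ships
a first-class synthetic-data generator that emits event tables at realistic
scale (7 sites, 78 × 30 species, 795 events, a dominant visit layer,
strongly skewed ant frequencies) with planted, recoverable structure: a
specialization knob, modular and nested fixtures, a shared boosted ant core
and disjoint per-layer plant cores.

## The statistics, briefly

With cell counts `a_ij`, row/column totals `r_i`, `c_j`, grand total `F`:

- **H2′** = (H2max − H2) / (H2max − H2min), where H2 = −Σ p_ij ln p_ij,
  p_ij = a_ij/F, and H2max/H2min are the extreme entropies attainable by
  integer matrices with the observed margins (exact by enumeration for
  F ≤ 12, heuristic fills above). 0 = interactions at the independence
  expectation, 1 = maximal specialization given the margins.
- **WNODF** ∈ [0, 100]: for each ordered row pair with strictly decreasing
  totals, the percentage of the poorer row's positive cells that are
  positive but smaller in the richer row; symmetrically for columns;
  averaged over all pairs.
- **Morisita-Horn** C = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²) on relative-use
  vectors; network value = mean over guild pairs.
- **Q** = Σ_ij [a_ij/F − r_i c_j/F²] δ(m_i, m_j) (Barber's weighted
  bipartite modularity), maximized by simulated annealing; significance as
  standardized Q = (Q_obs − mean Q_null)/sd Q_null over Patefield draws,
  flagged at ≥ 2.
- **Null model**: Patefield's algorithm draws uniform-conditional integer
  matrices with the observed margins; Monte-Carlo p-values use
  (1 + x)/(N + 1).
- **PERMANOVA**: one-way Anderson partitioning of squared distances,
  pseudo-F and R² with free label permutation (exhaustive enumeration
  available for small designs).

## Worked example

```bash
antweb synth --out events.csv --truth truth.json --seed 5
antweb run --events events.csv --out results/ --seed 1
antweb metrics --matrix results/matrices/EFN.tsv --metric wnodf
```

or from Python:

```python
from antweb import GeneratorConfig, generate, build_multilayer, h2prime, wnodf

events, truth = generate(GeneratorConfig(seed=1))
net = build_multilayer(events)
print(net.pooled)                     # LayerMatrix('multilayer', 68 plants x 22 ants, F=795)
print(round(h2prime(net.pooled).value, 3))             # 0.056
print(round(wnodf(net.pooled).value, 1))               # 46.1
print(round(h2prime(net.layers["trophobiont"]).value, 3))  # 0.201
```

The pooled multilayer network conserves all 795 generated events. Its H2′
of 0.06 says the pooled network is close to the margin-expected
(generalized) structure, while the trophobiont layer is markedly more
specialized (0.20) — the qualitative contrast these studies report. WNODF
46.1 indicates moderate weighted nestedness: poorer species' interactions
are partly ordered subsets of richer ones. `antweb run` writes
`report.json` (per-layer metrics with null summaries and p-values,
pairwise layer comparisons, descriptor GLMs, core membership, PERMANOVA,
NMDS stress) plus CSV tables and TSV/Pajek matrix exports; reruns with the
same seed are byte-identical.

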