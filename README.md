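# repertoire

Constraint-based analysis of the metabolic repertoires of host-associated
bacterial communities — built around the kind of question raised by the
*Caenorhabditis elegans* gut microbiota: what can each isolate eat and
secrete, which nutrients can the community synthesize, how do pairs of
isolates interact metabolically, and how do genome-scale traits relate to
adaptive strategy and colonization ability?

It is aimed at microbiome researchers who have (or can emulate) per-genome
metabolic networks and want a tested, scriptable pipeline for the analysis
half of that workflow — everything downstream of draft-model reconstruction.

## What it computes

* **FBA / FVA core** (`repertoire.fba_core`). Growth maximization subject to
  steady state `S·v = 0` and flux bounds (HiGHS LP); flux variability at a
  growth fraction; carbon-source utilizability (a source is *utilizable* iff
  the minimal flux of its exchange reaction is negative) and byproduct
  producibility (maximal exchange flux positive); auxotrophy scans via
  per-component demand reactions; futile-cycle detection (flux-capable
  reactions with all exchanges closed); parsimonious gap-filling (L1-penalty
  LP plus greedy pruning, minimality guaranteed by monotonicity).
* **Pairwise community FBA** (`repertoire.community`). Two models joined
  over a common extracellular pool, every internal reaction coupled to its
  member's growth (|v| ≤ c·μ, default c = 400), objective `max μ₁ + μ₂`
  with a deterministic max–min second stage. Pairs are classified from
  joint (j) vs monoculture (s) growth: mutualism (j₁>s₁ ∧ j₂>s₂),
  competition (both lower), parasitism (one up, one down), commensalism /
  amensalism (one unchanged), neutral.
* **Dynamic co-culture** (`repertoire.dfba`). Well-mixed explicit-Euler
  dFBA with metabolite pools, per-step uptake caps, and extracellular
  enzymes as independent species — e.g. a secreted sucrose invertase that
  lets a non-hydrolysing partner grow on sucrose.
* **Pathway presence** (`repertoire.pathways`). Reaction calls from homology
  hit tables (bitscore ≥ 50, conservative layer ≥ 150, coverage ≥ 0.75);
  pathway present iff completeness > 75 %, or > 66 % with key enzymes;
  essential-nutrient provisioning matrices with a community row.
* **Diversity** (`repertoire.diversity`). 16S percent identity (global
  alignment), pathway-vector distances, Spearman correlation of the two
  similarity structures with a Mantel permutation test, bootstrap-supported
  hierarchical clustering with newick export.
* **BIOLOG plates** (`repertoire.biolog`). Fold change
  `(OD_t46 − OD_t0)/OD_t0` minus the water-well background, substrate
  k-means (k = 7, best of 10³ restarts), Ward strain dendrograms with
  bootstrap, and (TP+TN)/total agreement between plate calls and model
  predictions.
* **Adaptive strategies** (`repertoire.uast`). Competitive / stress-tolerant
  / ruderal scores from cohort-relative quartile criteria, argmax
  assignment with ties → mixed, plus rank-sum and correlation tests against
  colonization load.
* **Association** (`repertoire.stats`). Per-trait Spearman correlation with
  a permutation null of random features, add-one empirical p, and
  Benjamini–Hochberg FDR.
* **Synthetic data** (`repertoire.synth`). Seeded generators with planted
  ground truth for every input above, so the whole pipeline runs and is
  tested without any external data.

## Worked example

```python
from repertoire import synth, fba_core, community

# toy chain model: uptake 10 mmol/gDW/h at yield 0.5 -> growth 5.0 1/h
model, medium = synth.make_chain_model(yield_=0.5, uptake=10.0)
print(fba_core.solve_fba(model, medium).objective)      # 5.0

# sucrose cross-feeding: the invertase bearer grows alone, the non-bearer
# only in co-culture
bearer, non_bearer, enzyme, sucrose = synth.make_invertase_scenario()
print(fba_core.solve_fba(non_bearer, sucrose).objective)  # 0.0
comm = community.join_models(bearer, non_bearer)
print(community.community_fba(comm, sucrose)[:2])         # (5.0, 5.0)

# medium-dependent interactions in a six-member community
members, rich, minimal = synth.make_six_member_community()
_, fractions = community.interaction_screen(members, rich)
print(fractions["competition"])                           # 1.0
_, fractions = community.interaction_screen(members, minimal)
print(round(fractions["parasitism"], 3))                  # 0.067
```

The chain optimum is the closed form uptake × yield; on the rich medium all
15 pairs compete for the shared finite carbon pool, while on single-carbon
minimal medium the dependency structure surfaces (parasitism via a stolen
shared substrate plus a secreted vitamin, commensalism via an acetate
byproduct).

The same stages are available from the shell:

```bash
repertoire synth suite --seed 1 --out suite/
repertoire fba --model suite/models/M1.json --medium suite/medium_minimal.csv
repertoire interactions --models suite/models --medium suite/medium_rich.csv --out pairs.csv
repertoire run --config config.yaml   # full pipeline
```

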