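# Methods

This note documents the models, procedures and numerical choices behind the
package, and what the synthetic-data generators do and do not emulate.

## Metabolic models and media

A model is a stoichiometric network with two compartments (cytosolic `c`,
extracellular `e`), flux bounds in mmol/gDW/h, and exactly one biomass
reaction whose flux is the growth rate (1/h). Exchange reactions are
single-metabolite boundary pseudo-reactions with coefficient −1, so negative
flux is uptake and positive flux secretion (the COBRA convention). A medium
is a map from extracellular metabolite to a maximum uptake rate; applying a
medium sets the exchange lower bound to −limit for listed metabolites and 0
for all others, leaving secretion bounds untouched (hence idempotent).
Namespaces are opaque strings: the package takes no position on reaction or
metabolite identifier systems.

The native format is JSON (or a metabolites/reactions TSV pair); a
read-only SBML-core subset (species, reactions, bounds via parameters) is
parsed directly rather than through a full SBML stack, because only the flat
network structure is needed.

## FBA, FVA and the screening rules

All linear programs are solved with HiGHS through `scipy.optimize.linprog`
over `S·v = 0` plus bounds; the solver is deterministic for a fixed problem,
and the tolerance used throughout for "zero" is `1e-6` (solver precision).

* *Utilizability*: a carbon source is utilizable iff, after granting it an
  uptake allowance (default 10 mmol/gDW/h), the **minimal** flux of its
  exchange is below −tol — i.e. net uptake is unavoidable somewhere in the
  feasible space, so a consumption route exists. By default no growth
  constraint is imposed: the question is whether the network *can* consume
  the compound. A `growth_fraction` flag switches to the growth-coupled
  variant (biomass ≥ fraction × optimum) for users who prefer that reading.
* *Byproducts*: producible iff the **maximal** exchange flux exceeds +tol.
* *Auxotrophies*: for each biomass component, a temporary demand reaction is
  maximized on the minimal medium with the component's extracellular
  counterpart removed; maximal demand ≤ tol marks an auxotrophy.
* *Futile cycles*: FVA with every exchange closed; any internal reaction
  with nonzero attainable flux is flagged. Reporting only — automatic bound
  repair is out of scope.

### Gap-filling

Given a universal reaction pool and a growth target, a first LP minimizes
the L1 norm of pool fluxes subject to biomass ≥ target (pool variables are
split into positive and negative parts). The support of that solution is
then pruned greedily in lexicographic reaction-id order: a reaction is
dropped whenever the remainder still reaches the target. Because adding
reactions can only increase the achievable optimum, a set from which no
single reaction can be removed is also inclusion-minimal, so the pruned set
is a genuinely minimal solution; tests verify this against exhaustive subset
enumeration for pools up to 12. Lexicographic pruning makes ties among
equally minimal sets deterministic. An LP/pruning approach was chosen over
MILP to avoid a MILP dependency; minimality is enforced by the pruning
argument rather than by integer optimality.

## Pairwise community growth and interaction labels

Two models are joined by merging extracellular metabolites into one shared
pool, namespacing everything else per member, and replacing member exchange
reactions with a single community exchange per pool metabolite (the medium
applies at the community boundary). Every internal member reaction `v` is
coupled to its member's growth, `−c·μ ≤ v ≤ c·μ`, which prevents a
non-growing member from running pathways that only serve its partner. The
coupling coefficient is not identifiable from first principles; the default
c = 400 follows the convention of the community-coupling literature, and the
test suite asserts that planted interaction labels are unchanged for
c ∈ {100, 400, 1000}.

Community growth maximizes μ₁ + μ₂. That optimum is frequently degenerate
(identical competitors can split a shared resource arbitrarily), so a second
stage fixes the optimal sum and maximizes min(μ₁, μ₂); the reported (j₁, j₂)
is therefore a deterministic, symmetric-when-possible split, and tests check
that the stage-2 solution reproduces the stage-1 sum to 1e−6. Monoculture
rates s are computed on the identical medium with the same coupling applied
to the single member (via an inert partner), so j vs s differences reflect
the partner, not the formulation.

Labels: mutualism (both improve), competition (both decline), parasitism
(one up, one down), commensalism (one unchanged, one up), amensalism (one
unchanged, one down), neutral (both unchanged). The last three require an
equality tolerance: |j − s| ≤ eps·max(s, 1e−9) with eps = 1e−6 relative.
Amensalism and neutral complete the label space for combinations the named
four do not cover, making the classifier total.

Exchanged metabolites are read from the stage-2 optimum as pool metabolites
with opposite-signed member-level net rates; the transferred amount is
min(|secretion|, |uptake|).

## Dynamic co-culture

The dynamic simulator is a well-mixed explicit-Euler dFBA: per step each
member's exchange uptake bound for metabolite m is
`min(vmax, conc_m / (X_total·dt))` — the division by *total* biomass
guarantees the pool cannot be overdrawn even if every member draws its
maximum — each member's LP is solved independently, then biomass
(`X += μX·dt`) and pools (`conc += v_ex·X·dt`) are updated. Extracellular
enzymes are independent species with a single conversion among pool
metabolites running at `rate_constant × abundance`, capped by substrate
availability, with fixed abundance (no synthesis or decay) — the simplest
faithful reading of a secreted enzyme as its own species. Negative pools
are clamped at zero and counted; at the default dt = 0.05 h clamping is rare
(< 1 % of steps on the shipped scenarios). Defaults: vmax = 10 mmol/gDW/h,
dt = 0.05 h.

A spatial lattice simulation (grid, diffusion, cell placement) is *not*
reproduced: the qualitative co-culture conclusions exercised here — growth
rescue of a non-hydrolysing member by a partner's secreted invertase — do
not depend on space, and the well-mixed formulation keeps the simulator
deterministic. Because pool updates and biomass updates use the same LP
fluxes, elemental balances are conserved up to clamping; the test suite
tracks carbon on fixtures with known atom counts and requires closure
within 1 %.

## Pathway presence

Reaction presence from hit tables: any hit with bitscore ≥ 50 and query
coverage ≥ 0.75 (inclusive thresholds); a conservative layer repeats the
call at bitscore ≥ 150. Pathway presence: completeness > 0.75, or
completeness > 0.66 with key enzymes present — completeness thresholds are
strict inequalities, mirroring the operators of the rule exactly, which is
why a 3-of-4 pathway (0.75) is *absent*. "Key enzymes present" defaults to
*all* key enzymes (stricter reading); `key_mode="any"` is available.
Conservative presence implies standard presence (monotone in the bitscore
threshold), and raising the coverage floor can only remove presences; both
properties are tested on randomized fixtures. Sequence search itself is out
of scope — hit tables are inputs.

## Diversity

16S similarity is percent identity from global pairwise alignment (match
+1, mismatch −1, gap open −2, extend −0.5; fixed, documented package
defaults) with the denominator counting all alignment columns including
gaps (an `aligned`-columns variant is selectable). Metabolic similarity
treats pathway presence vectors as binary vectors: Euclidean distance for
clustering, and the simple matching coefficient (fraction of agreeing
calls) as the similarity analogue of percent identity.

The two similarity structures are compared by Spearman correlation over
upper-triangle entries with a Mantel permutation test: rows and columns of
one matrix are permuted simultaneously, because pairwise entries are not
exchangeable individually; p = (1 + #{|ρ_perm| ≥ |ρ|})/(n_perm + 1),
two-sided. Clade support is a plain bootstrap proportion over pathway
columns rather than a multiscale approximately-unbiased bootstrap: the AU
machinery adds multi-scale resampling peripheral to what the support values
are used for here, and the plain proportion is directly interpretable.

## BIOLOG analysis

Per replicate well, the raw fold change is `(OD_t46 − OD_t0)/OD_t0`; the
water well's *fold change* (not its raw OD) is subtracted as background —
the subtraction must be on the fold-change scale for the water well itself
to score 0 — and the three replicates are averaged. Binarization uses a
fold-change cutoff of 1.0 by default (the positive-call threshold is not
canonical; it is exposed and a sensitivity check lives in the tests).
Substrate k-means (k = 7 by default) takes the best of 10³ seeded
initializations by within-cluster SSE; strain dendrograms use Ward linkage
on Euclidean distances with bootstrap over substrates (n = 100).
Model-vs-plate agreement is (TP + TN)/total over the shared substrate
universe, symmetric in its arguments.

## Adaptive-strategy (C/S/R) scoring

Each isolate is scored relative to its cohort. Competitive criteria (4):
upper quartile of genome size, antibiotic-biosynthesis pathways, catabolic
diversity (energy-metabolism pathways) and siderophore pathways.
Stress-tolerance criteria (4): upper quartile of auxotrophies and EPS
pathways, lower quartile of rRNA copies, growth rate below the cohort mean.
Ruderal criteria (3): growth above the mean, upper quartile of rRNA copies,
lower quartile of catabolic diversity. Scores are points divided by the
criteria count per strategy (4/4/3), the assigned strategy is the argmax,
and any tie of the top scores — two- or three-way — is "mixed". "Quartile"
uses the 25 %/75 % cut with inclusive membership (≤ Q1, ≥ Q3), making the
scoring invariant under positive rescaling of any trait; growth rate uses
the mean split as the stated exception for that criterion.

## Trait–phenotype association

Per binary trait, Spearman ρ against the phenotype; the null distribution
comes from randomly generated features — prevalence-preserving permutations
of the trait column by default (a matched-prevalence Bernoulli mode is
provided), since "random feature" is otherwise underdetermined. The
empirical p uses the add-one rule, p = (1 + hits)/(n_random + 1), so p is
never zero, and q-values are Benjamini–Hochberg step-up across traits. The
API default of 100 random features gives a p granularity of 1/101; analyses
that need q < 0.05 after FDR across tens of traits should use ≥ 999 (the
tests and the acceptance script do). The rank-sum utility enumerates the
exact null for combined n ≤ 20 without ties and otherwise uses the
tie-corrected normal approximation.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its seed and returns (or writes) its
planted truth. Toy models are ≤ 25 reactions so closed forms, hand LPs and
exhaustive enumeration remain checkable. The media fixtures mirror the
*structure* of a rich isolation medium (several finite carbon sources plus
a vitamin) versus a single-carbon minimal medium — not any real
composition. The six-member community plants one vitamin-mediated
parasitism, one byproduct commensalism, shared-resource competition and
non-grower neutrality, so the label mix flips with the medium by
construction.

The 16S/pathway generator evolves sequences down a random bifurcating tree
whose branch lengths shrink geometrically with depth — the genus-versus-
strain block structure of real communities — and couples a calibrated
fraction f of pathway columns to the same tree, the rest to an independent
tree. f is set from the target correlation by a variance-matching mixture
argument, f/(1−f) = ρ/√(1−ρ²); finite sequence length and pathway count
attenuate the realized correlation slightly, which the ±0.1 recovery band
absorbs. UAST cohorts draw traits around three archetypes with 15 %
relative Gaussian noise (counts rounded and clipped); phenotypes are linear
in the planted effect traits with unit-sd noise.

What passing tests do **not** show about real data: generators plant clean,
low-dimensional structure (single planted effects, well-separated
archetypes, block pathway structure) and model fluxes with exact mass
balance; real genome-derived networks carry annotation noise, database
version dependence and correlated traits that these fixtures deliberately
avoid. Quantities that depend on a specific strain collection and database
(overall interaction-type percentages, strategy counts, observed 16S–
metabolic correlation strength) are design-dependent here, not predictions.

## Known limitations

Communities larger than two members are simulated dynamically but not as a
single coupled LP; there is no community-level FVA; no thermodynamic
(loopless) FBA; gap-filling is heuristic-LP rather than MILP (with
minimality guaranteed by pruning); SBML support is read-only and partial;
the dynamic simulator has no spatial structure and no enzyme
synthesis/decay.
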