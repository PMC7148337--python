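# Methods

This note documents the models and procedures implemented in `orthogem`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study does and does not demonstrate.

## Constraint-based core

All analyses operate on a steady-state stoichiometric model: metabolites,
reactions with bounds in mmol·gDW⁻¹·h⁻¹, Boolean GPR rules and one biomass
objective.  Exchange reactions are single-metabolite drains written
`met →`, so uptake is negative flux and a medium makes a nutrient available
by setting a negative lower bound (BIGG convention).  LPs are solved with
scipy's HiGHS backend, single-threaded; solutions are deterministic for a
fixed model, but only objective values are contractual — the optimal face
can be degenerate and alternate optimal flux vectors are accepted.

Numerical tolerances: fluxes below `1e-6` count as "almost zero"
(blocked-reaction detection, functional-test objectives, essentiality
guards).  This matches community practice on ±1000-bounded networks, where
the solver's feasibility tolerance (~1e-9) leaves three orders of margin.
Mass-balance residuals of accepted optima stay below 1e-6 per metabolite
(asserted in the test suite).

FVA at objective fraction 0 probes pure feasibility; this is the mode used
for blocked-reaction detection, performed with every exchange opened to
±1000 so that a reaction is called blocked only for structural reasons,
not because of the current medium.  Dead-end metabolites are those the
non-blocked reactions cannot both produce and consume, with reversibility
taken into account.

## Orthology translation and curation

Each GPR leaf translates to its orthologue set: one target → plain leaf,
k > 1 targets → OR over all k.  OR is the permissive standard for
orthology-transferred GPRs; a per-gene `resolved` override in the mapping
table substitutes a single curated target when one-to-many relations have
been manually adjudicated.  A leaf with no orthologue becomes an explicit
FALSE-marker rather than being deleted, so classification and curation can
see exactly which genes failed; markers are pruned only when curation is
applied (dropped under OR; a marker that would falsify a core reaction's
GPR is an error rather than a silent deletion).

Classification treats orthologue existence as a truth value per gene:
reactions with no GPR are NGA, satisfiable ones GAHM, falsified ones GAH.
Every GAH reaction must carry a curation decision — keep with corrected
GPR (re-translated through the map), remove entirely, or demote to
non-gene status.  Demoted reactions keep their original bounds; nothing in
the demotion concerns capacity, only gene evidence.  Biomass and ATP
maintenance are designated artificial core reactions by id.  Curated
species-specific additions may introduce new metabolites; any of these left
structurally dead-ended get an auto-generated reversible sink so additions
cannot create dead ends.

## Gap filling and assembly

The minimal model must let every core reaction carry |v| ≥ ε individually
(ε = 1e-4 — far above flux tolerance, far below typical optima).  The gap
filler is an LP sweep in the FASTCORE family rather than an exact MILP set
cover: per unsatisfied core reaction it minimises the weighted L1 support
over candidate reactions subject to that core reaction carrying ≥ ε flux
(both directions tried, cheaper support kept), unions the supports, then
compacts the result by attempting to drop each added reaction in
lexicographic order.  The output is therefore inclusion-compact by
construction; global minimum cardinality is verified against exhaustive
subset enumeration only on small instances in the test suite, where the
two have so far coincided.  Ties between equally cheap candidates resolve
lexicographically, making the result deterministic.  Candidates that are
known to be required for reference consistency (demoted GAH reactions) can
be given weight 0, making them free to select.

Core reactions that cannot reach ε even with every candidate are reported
as unfillable and the result is flagged not certified; they are never
silently dropped.

The maximal model is simply core ∪ all non-core.  Min and max models share
the gene-associated reaction set by construction and, when the reference
was flux-consistent, both assemble with zero blocked reactions and zero
dead ends (a pipeline property asserted in the acceptance suite).

## Functional tests

MCTs supply each source metabolite through a bounded sink (−1000, 1000)
and drain each target through a demand (0, 1000), added only when no
boundary reaction already exists, under the named medium with all other
uptakes closed.  The summed target demand is maximised; with several
targets each one must also individually exceed tolerance — the aggregate
alone could hide a dead target behind a productive one.  ROTs close
organic exchanges (carbon in the formula decides "organic"; a config list
substitutes when formulas are absent — inorganic exchanges stay open),
re-open the allowed substrates, set oxygen uptake by the aerobic /
anaerobic condition and maximise the named reaction.  Both kinds fail in
exactly one of three modes: missing component, no optimal solution,
almost-zero optimum.  Tests never mutate the input model; scratch sinks
and demands live in a per-test copy.

## Expression processing

Sample QC follows the iterative correlation z-score: per round, Pearson
correlations between all sample pairs, per-sample mean correlation x_i,
z_i = (x_i − x̄)/s with the n−1 standard deviation, removal at |z| ≥ 2
(inclusive, reading "two and more standard deviations" as ≥), repeated
until no removal.  Constant samples, whose correlation is undefined, are
removed with an explicit reason.  When the remaining samples are
equi-correlated the spread of mean correlations collapses to rounding
error; a spread below 1e-12 stops the loop rather than dividing rounding
errors by each other.  QC runs before binarization (the pipeline default;
the ordering is not dictated by the procedure itself).  An optional flag
computes correlations on log2(x+1) for raw-scale intensities.

Calls binarize P→1, M→0, A→0; multi-probe genes collapse by per-sample
maximum; unmapped probes are dropped with a logged count.  Gene ubiquity
is the row mean over retained samples; model genes absent from the
platform get frequency 0 with a warning.

## Tissue extraction (modified mCADRE)

Expression scores propagate ubiquity through GPRs with AND→min and OR→max
— the published mCADRE convention, respecting complex/isozyme semantics.
Connectivity scores are the mean expression score of adjacent reactions,
where adjacency means sharing a non-currency metabolite; the currency list
(h, h2o, atp, adp, pi, nad, nadh, compartment-stripped) avoids degenerate
all-to-all adjacency through cofactors.  Core = expression score at or
above the threshold (inclusive); non-core reactions are removed worst-first
(ascending expression, then ascending connectivity, then id).  Reaction
confidence scores are not part of the ranking.

Each tentative removal is rolled back if (a) any key metabolite stops
being producible from glucose under the pruning medium — implemented as
per-metabolite conversion tests, with the key-metabolite list a
configuration choice (pyruvate in the shipped analysis; the procedure
itself fixes no list), (b) any core reaction becomes blocked, or (c) the
biomass optimum under the growth medium falls below 80% of the
genome-scale model's optimum — the biomass-production guard layered on
top of classic mCADRE's function and consistency checks.  The trace
records every candidate with its outcome and reason, and identical inputs
give identical traces.  mCADRE's salvage/rescue rules tied to confidence
scores are intentionally not implemented.

## Essentiality

Knockouts shut every reaction whose GPR is satisfied with the full gene
set but falsified without the deleted gene.  FBA re-maximises biomass;
linear MOMA minimises Σ|v_w − v_d| with positive/negative split variables
against the wild-type optimum, without re-optimising growth, and the
mutant's biomass is read off the distance-minimising flux vector.  The
wild-type anchor is the deterministic solver's optimal vertex, recorded in
outputs because the optimal face may be degenerate.  An infeasible mutant
reports objective 0 by convention.  Essentiality uses strict `ratio < 0.30`
against the same-medium wild type.  Genes absent from a model are skipped
and excluded from its confusion matrix, with the skip count reported, so a
model covering only part of a screened gene list is judged on the genes it
contains.  Sensitivity/specificity percentages round half-up to integers.
Quadratic MOMA is out of scope.

## Synthetic study design

The generator emulates the *shape* of a reference-based reconstruction
study at desk scale: models of ~45–65 reactions and ~30–50 genes — large
enough for non-trivial gap filling and pruning, small enough that
exhaustive oracles (truth tables, subset enumeration, per-gene knockout
sweeps) finish in seconds.  The topology is fixed (glucose uptake,
capacity-limited glycolysis, fermentation vs. oxygen-dependent
respiration across an optional mitochondrial compartment, nutrient
pathways feeding biomass precursors, redundant de-novo routes for
even-numbered pathways); the seeded randomness governs GPR structure,
gene assignment, the non-core fraction, orthology coverage and expression
sampling.  Glycolysis is capacity-capped at 50 so that aerobic and
anaerobic ATP yields differ, keeping the respiration ROT strictly
informative.  Default fractions: 20% of eligible reactions stripped of
GPRs (non-core), 8% of genes unmapped, 15% one-to-many, 70% of genes
tissue-active; calls are Present with probability 0.9 (active) / 0.1
(inactive).  Media: the rich medium opens every nutrient exchange at
±1000; the lean medium omits the even-numbered nutrients, which the
de-novo routes compensate for.

Ground truths come from independent machinery — a local recursive GPR
evaluator and a dense LP with equality encoded as paired inequalities —
never from the pipeline modules under test.

Regular expression arrays measure one underlying transcriptome up to a
per-sample affine gain/offset, so their pairwise Pearson correlations are
exactly 1, while planted outliers draw an independent activity pattern.
This makes QC recovery exact and the stopping condition sharp.  It is the
main idealisation of the generator: real arrays carry biological and
technical noise beyond gain/offset, so passing QC tests here demonstrates
the mechanics of the iterative z-score (including multi-round unmasking,
which is exercised with hand-constructed noisy fixtures), not its error
rates on noisy data.  Likewise, call noise is independent across samples
and probes, pathway lengths are short, and metabolite chemistry is
schematic — formula strings exist only to drive the organic/inorganic
closure policy.  Essentiality recovery on these models shows the
deletion machinery is correct, not that 30% is the right threshold for
any real organism.

## Known limitations

- The gap filler guarantees compactness, not global minimality; the gap is
  quantified (and so far zero) only on enumerable instances.
- Pruning re-checks all core reactions after each tentative removal; this
  is quadratic in model size and intended for desk-scale models, not
  10k-reaction reconstructions.
- SBML support covers Level 3 FBC v2 as produced by the package and by
  COBRA-style exporters; group/annotation layers are ignored.
- The linear MOMA anchor is a single optimal vertex; flux-sampling or
  parsimonious anchors would change mutant predictions on degenerate
  networks.
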