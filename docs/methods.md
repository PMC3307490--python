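# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about behaviour on real data.

## Source-tree standardization

Source trees are standardized against a reference species list via a
registry of synonyms (alias → valid name, or a DELETE sentinel), and
higher-taxon terminals are replaced by their name-bearing type species where
one is registered, otherwise pruned. Leaves flagged DELETE are pruned, and
because such leaves typically are non-ingroup taxa that positioned the root,
their presence marks the standardized record as rooted. When synonymy leaves
one species on k > 1 leaves, one record per placement permutation is emitted
(the species kept at exactly one position at a time) so each record can be
down-weighted by the permutation count, conserving the original tree's total
evidential weight. The cartesian product over duplicated species is capped
(default 64 permutations); past the cap only the first-encountered placements
are kept, with the permutation count reset to 1, and the event logged — an
uncapped blow-up is combinatorial and the information content of extreme
permutation sets is negligible per tree.

Sequence-metadata filtering keeps records at least 200 bp long (50 bp for
tRNAs) with at most 5% undefined bases, retains at most the 10 longest
*distinct* lengths per species-gene pair (each length may cover several
sequences), and drops genes left with 20 or fewer species. Consensus
selection picks the sequence with the fewest mismatches against the
column-majority consensus; ties (in column majorities and in distances)
resolve by input order, deterministically, and are logged. Pairwise overlap
screening requires 100 shared non-gap, non-N columns (20 for tRNAs) and
prunes greedily, removing the sequence with the most failing pairs (then the
least total overlap) until all pairs pass.

## MRP encoding and weighting

Each informative internal node (the root excluded) of a standardized source
tree becomes a partial binary character; semi-rooted coding scores the
fictional outgroup 0 on rooted trees and missing on unrooted ones, so the
outgroup behaves like any other taxon during the search and is pruned from
reported supertrees.

Weights have units of bootstrap percentage. The base weight is the node's
bootstrap when present, else the mean bootstrap over all support-bearing
characters in the matrix (neutral weighting); if no character in the matrix
carries support, the base is 1. The base is divided by the number of distinct
source trees in the character's literature data category — one global divisor
per category, the most conservative reading of non-independence, since it
assumes complete redundancy within each category; gene trees are never
category-down-weighted — and by the record's permutation count. Seed-tree
characters finally receive (minimum non-seed weight)/10, so any real source
tree can overrule the taxonomy. Weights are stored as reals; the NEXUS
writer additionally emits a ×1000 integer rendering for parsers requiring
integer weights, and the matrix (states, weights, per-character provenance)
round-trips losslessly through the package's own reader.

## Parsimony search

The weighted parsimony length is Σ_c w_c · (minimum state changes of
character c), computed by a two-state Sankoff dynamic program vectorized over
characters; this is exact on multifurcating trees and treats `?` as free.
Score ties are detected at relative tolerance 1e-9.

Rooting every candidate at the outgroup maps the unrooted search space
one-to-one onto rooted binary trees over the real species. The search is a
parsimony ratchet: each iteration doubles the weight of a random 25% of
characters, hill-climbs under the perturbed weights, then under the original
weights (rooted NNI moves, steepest ascent). Each batch ends with a
conventional heuristic polish that alternates full SPR sweeps with NNI climbs
until neither improves — the SPR neighbourhood is what lets the search leave
NNI-stable optima. When no user start tree is given, the first batch starts
from a greedy random-addition-sequence tree and later batches restart from
fresh addition orders; when a seed/taxonomy tree is supplied it is the start
tree throughout (its polytomies randomly resolved). All topologies tying the
best score are retained up to a cap (default 10,500, which simply truncates
the tie set), expanded by a breadth-first sweep of equal-score NNI neighbours,
and summarized by their strict consensus. The desk-scale default is 5 batches
× 50 iterations; the original study's 50 × 200 is available through the
configuration. TBR swapping is not implemented; the accuracy guarantee is
exhaustive-enumeration equivalence on small instances (tested over all 945
seven-taxon unrooted topologies) and exact recovery of single-tree matrices.

## Support and distance

A source scores +1 for a supertree node when, after restricting both to their
shared taxa, the node's bipartition occurs in the source; −1 when the source
holds an incompatible bipartition (all four side intersections non-empty —
the strictest testable reading); 0 when the node collapses on the shared
taxa, the source shares fewer than 4 taxa, or the source is compatible but
unresolved. rQS per node is (support − conflict)/(support + conflict); the
tree-level summary is the mean and standard error over nodes with a defined
value. All comparisons use unrooted bipartition semantics, matching the
semi-rooted matrix philosophy. The normalized partition metric divides the
count of bipartitions in exactly one tree by 2(n−3); resolution is
(internal nodes − 1)/(n − 2) for a rooted n-leaf tree.

## Divergence dating

A node's depth in a gene tree is its mean path length to descendant leaves;
relative height is depth normalized by root depth (exact clock heights on
ultrametric input). Each calibration whose clade is monophyletic in the gene
tree fixes a scale (calibration age / relative height), and every gene ×
calibration combination yields one estimate per node; estimates at
calibration nodes are clamped to the calibration's hard bounds (range
calibrations use the midpoint as the age and the extremes as bounds) before
pooling. Per target node the central value is the bootstrap-weighted mean of
the pooled estimates — the median is available by configuration, and both
descriptions circulate for this family of methods, so the choice is explicit
rather than silent. A fossil age at the node overrides a younger central
value (flagged `fossil-override`); the 95% CI is the 2.5th/97.5th percentile
of the pooled distribution, with fossil ages pooled in. Nodes without any
estimate are interpolated top-down from clade sizes under a pure-birth model:
below the nearest dated ancestor of age T subtending m species, a node
subtending k species receives T·ln k/ln m. The published formulation of this
interpolation is ambiguous between log-proportional and expectation-based
forms; the log form is implemented and isolated in one function, and its
output is cross-checked against simulated pure-birth expectations in the
tests. Children older than their parents are clamped to the parent's age
(zero-length branches) in pre-order, idempotently. Output trees are always
ultrametric with leaves at 0.

The likelihood fitting of sequence data onto a reference topology is out of
scope: the module consumes gene trees with branch lengths from any inference
tool, and the synthetic generator provides them for testing.

## Macroevolutionary statistics

γ follows the standard normalization of cumulative internode intervals
(two-tailed p from the standard normal) and requires a binary tree —
polytomies must first be resolved under the equal-rates-Markov draw
(sequential random joins; new nodes dated uniformly between the polytomy's
age and its oldest child, assigned in age order). Segmented regression fits
ln(lineages) against time with 0–2 breakpoints, breakpoints searched
exhaustively over observed event times with continuity enforced by a hinge
basis, and the model minimizing AIC = n·ln(RSS/n) + 2(2 + 2·breakpoints)
selected; the RSS is floored at numerical-noise scale (n·1e-16) so exact fits
cannot let spurious extra breakpoints win on floating-point dust. Binned net
diversification uses events/exposure per bin (default width 0.25 Ma), the
maximum-likelihood pure-birth rate; a simpler log-count-difference estimator
is available by configuration. Slowinski–Guyer is 2·min(r,s)/(r+s−1) capped
at 1. Family correlations are Pearson r of species richness against crown
age, origin age and % lag with two-tailed p from the t distribution on n−2
degrees of freedom; monotypic families have no crown age and are excluded
from such tables by construction.

## Conservation scores

Species-level PD is reported as the terminal branch length, matching the
published species tables (each species' unshared history); clade PD is the
minimal spanning subtree length with an optional stem branch. Fair-proportion
ED divides each branch by its number of leaf descendants; the root stem
(from the root's age back to a stem age) is shared among all species and is
included when requested — numerically this stem-inclusive convention is what
reproduces the published per-species ED values, and the package exposes both
conventions because the published whole-tree PD totals differ between the
stem-inclusive and stem-exclusive readings. EDGE is ln(1+ED) + GE·ln 2 with
GE = 0,1,2,3,4 for LC, NT, VU, EN, CR; Data Deficient species score 0 and
share the bottom rank. Ranks are descending with ties sharing the best rank
and the following rank skipped.

## Synthetic data: what it emulates, and what it does not

The generator's defaults describe the standard recovery scenario: a
40-species pure-birth truth at λ = 0.2/Ma, 30 literature records that each
subsample 40% of the species and suffer one random NNI error (no supports,
12% rooted — literature trees are overwhelmingly unrooted in this
literature), six gene trees covering 75% of the species with lognormal
per-branch rate noise (σ = 0.2) and per-gene rates (σ = 0.5), bootstrap
values drawn from a Beta(8,2) scaled to [50,100] on true clades, a taxonomy
seed tree made by collapsing half the true tree's internal nodes, one exact
calibration at the root, and a Red List composition of roughly half Least
Concern species. Pure-birth trees conditioned on n species are built directly
from their interval distribution (g_k ~ Exp(kλ)), which is also the exact
null of the γ test; birth–death trees with extinction are simulated forward
and retried until n lineages are extant.

NNI-level topological error keeps the simulated literature in the
mostly-compatible regime that positive published rQS values indicate; the
generator does not emulate systematically conflicting data sources, character
data (no sequence simulation — branch-length-level emulation suffices for
every consumer here), non-random taxon sampling, or calibration biases.
Passing the recovery tests therefore shows the pipeline is internally
consistent and accurate under its own assumptions, not that any real
supertree is correct.

## Problem sizes and seeds

The test suite and examples run at desk scale by choice: 20–50-species
scenarios, ratchet configurations of 2–5 batches × 8–50 iterations, 500
pure-birth replicates for the γ type-I calibration, and 100 random trees for
the encode/decode round trip. All randomness flows from explicit integer
seeds (Python `random.Random` and NumPy generators), and identical
configuration plus seed reproduces byte-identical pipeline outputs, which the
manifest's file hashes make checkable.

## Known limitations

- The ratchet's moves are rooted NNI plus SPR polishing; TBR is absent, so
  very rugged matrices may need more batches/restarts than the defaults.
- rQS scores compatible-but-unresolved sources as equivocal (0); excluding
  them beforehand would change node denominators.
- The MP tie-set cap truncates (with a log message) rather than summarizing;
  consensus trees computed from a truncated set can be over-resolved.
- Clade-level ED (for higher taxa) is not implemented; its published
  definition is not recoverable from the species-level tables.
- The dating CI pools fossil ages with genetic estimates; percentiles from
  genetic estimates alone would be narrower at fossil-overridden nodes.
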