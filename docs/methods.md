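# Methods

This note records the scientific model behind each module, the parameter
choices and their rationale, what the synthetic generators do and do not
emulate, and the numerical conventions, so that results produced with the
toolkit can be interpreted precisely.

## Scores

**Residue identity.** Every residue is identified by the pair (sequence id,
ungapped residue ordinal).  Scores therefore compare *which residues share a
column*, never characters: two alignments of the same sequences cannot alias
one residue for another however gaps move.  Columns that are all-gap across
the scored rows carry no information and are ignored on both sides; this is
what makes SP and TC invariant under all-gap column insertion and row
reordering, which the property tests assert.

**SP** = |pairs(reference) ∩ pairs(test)| / |pairs(reference)|, where a pair
is two residues of different sequences sharing one column.  Residues aligned
against gaps are unscored.  A reference with zero aligned pairs produces an
*undefined* score, serialized as NA — never 0, because a spurious 0 would
poison family averages downstream.

**TC** = shared columns / reference columns, where a reference column is
shared iff some test column holds exactly the same residues-and-gaps pattern
over the scored sequences.  TC = 1 implies SP = 1.

**SSPA** compares predicted and known 3-state (H/E/C) secondary structure
strings over the ungapped residues of each reference.  The pooled score is
total matches over total positions across references, so longer references
weigh proportionally more; per-sequence accuracies are returned alongside so
a mean-of-means can be recomputed if preferred.  The predicted string is
assumed total over residues (no no-call state).

## Effective guide-tree and re-rooting

The effective guide-tree of a rooted binary guide-tree with respect to a
reference set is the most recent common ancestor clade of the references;
its leaf count (the *effective size*) bounds how much of the alignment the
SP score can probe under progressive alignment.

`reroot_for_effective_size` guarantees a minimum effective size.  The
guarantee rests on a topological fact: rooting on any edge of the minimal
spanning subtree connecting the references splits the references across both
root children, so the MRCA is the root and the effective size equals the
total leaf count.  Hence for any threshold up to the leaf count a passing
rooting exists, and the search cannot fail on valid input.  Two strategies
are offered:

- `first-passing` (default): candidate rootings — one per edge of the
  unrooted topology, 2n−3 for n leaves — are scanned in seeded random order
  and the first rooting whose effective size meets the threshold is
  returned.  An already-rooted input that passes is returned unchanged.
  This mimics a "re-root until the size exceeds the threshold" loop while
  staying reproducible: the seed is part of the configuration and recorded
  in provenance.
- `maximize`: deterministic exhaustive scan returning the maximal effective
  size, ties broken by enumeration order.  Used as the oracle-comparable
  mode and wherever strict determinism without a seed matters.

The default threshold is 900 out of 1000 taxa, the published operating
point for embedded families of 1000 sequences; both numbers are ordinary
configuration values.

Multifurcating trees (some aligners emit them) are binarized before
enumeration — child order shuffled under the configured seed, then folded
pairwise with zero-length edges — because the size arguments assume binary
merges.  Branch lengths play no role in any size computation; they are
carried along only so Newick round-trips are faithful, with the edge under a
new root split 50/50.

`reference_balance` summarizes how evenly references sit in the tree: the
min/max ratio of reference-containing child-clade sizes at the MRCA, plus
the per-pair child-clade splits.

## Distance space and selection

**Distance.** d(i,j) = 1 − (identical residues) / (mutually ungapped
columns), the standard percent-identity distance computed from an existing
family alignment.  A pair sharing no residue columns gets d = 1 with a
warning.  The toolkit never aligns; alignments or distance matrices are
inputs.

**Embedding.** Classical (Torgerson) scaling: double-center the squared
distance matrix, take the top-d eigenpairs, truncate negative eigenvalues to
zero.  Exact for distance matrices Euclidean-realizable in the target
dimension (the fidelity tests require 1e-6 agreement); indefinite matrices
are approximated through the centered Gram matrix.  The embedding is used
for inspection and fixtures; selection itself works on raw distances.

**Reference selection** maximizes the sum of pairwise distances of the
chosen k-subset (the triangle perimeter for k = 3).  Perimeter was chosen
over triangle area because area collapses for collinear-but-distant triples
that are still good spreads, and perimeter is monotone in every pairwise
distance.  Candidate sets of ≤ 25 are searched exhaustively (lexicographic
tie-break); larger sets use greedy farthest-point construction with 8 seeded
restarts and a swap-improvement pass, which the tests require to agree with
the exhaustive optimum in ≥ 90% of random 10-candidate pools.

**Non-reference categories.** Every candidate receives three scores:
nearest-reference distance, margin (second-nearest minus nearest), and the
minimum triangle-inequality deviation δ(x; a,b) = d(a,x)+d(x,b)−d(a,b) over
reference pairs (δ ≥ 0 for metric distances; δ = 0 means exactly
"between").  A candidate is assigned the category in which its rank among
all candidates is best — ascending nearest distance for the neighbourhood
class, descending margin for near-one-far-two, ascending δ for between —
with rank ties resolving toward the neighbourhood class.  Family assembly
draws non-references round-robin from the three category rankings (ties on
score broken by id) until the target count is reached, keeping per-category
counts within one of each other.  Defaults are k = 3 references and a
family size of 1000, i.e. 997 non-references.

## Regression and ranking

Per-family fits of SP on SSPA use closed-form ordinary least squares.  For a
model linear in its parameters an iterative least-squares optimizer
(e.g. Levenberg–Marquardt) converges to the same optimum, so the closed form
is an exact replacement that avoids iteration nondeterminism.  Families with
zero SSPA variance are flagged *singular* and carry no slope; they are
tallied separately from the slope CDF, never coerced to zero.  Residual
spread is summarized as RMS (same units as SP) with the raw sum of squares
alongside.  Two usable points are accepted (the fit is then exact with zero
residual).

Aligner ranking averages replicates within each family first, then across
families, over a family set made identical for all aligners by listwise NA
dropping.  Because the averaging order is a genuine ambiguity, the pooled
all-rows mean is also emitted (`pooled_mean_*` columns).  Pearson and
Spearman (average-rank ties) correlations between per-aligner mean SSPA and
mean SP require at least three aligners, otherwise NA.

Input-order shuffling emits the original ordering first plus n seeded
uniform permutations — n_shuffles = 100 turns one input set into 101
alignments once an order-sensitive aligner is applied.

## Synthetic data

`generate_family` evolves a uniform-random root sequence down a
coalescent-style random binary topology (uniform pair joins).  Per branch,
each site substitutes with probability `substitution_rate` (default 0.05)
and indel events arrive Poisson with mean `indel_rate · length` (default
0.02 per site), with geometric lengths (p = 0.5, mean 2) and equiprobable
insertion/deletion; deletions never empty a sequence.  Every inserted column
is spliced into a single global column order, so the simulation yields the
true alignment by construction and gap-stripping it reproduces the unaligned
records exactly.  Secondary structures are 3-state Markov chains
(self-transition 0.8) independent of sequence content; predicted variants
redraw each position uniformly over {H,E,C} with probability
`prediction_corruption`, so corruption 1 leaves expected agreement at the
1/3 chance level — the baseline the acceptance checks verify.  Defaults
(100 sequences of mean length 150, 3 annotated) are a desk-scale stand-in
for real families of 10–1000 homologs with 3 structural references.

What the generator does *not* emulate: realistic amino-acid substitution
processes (no WAG/LG matrices), rate heterogeneity, affine gap penalties,
structure–sequence coupling, or alignment difficulty gradients.  Passing
tests therefore certify the *bookkeeping* of the toolkit — scores, tree
operations, selection geometry — not any claim about aligner behaviour on
biological data.

`generate_planted_distances` builds exact 2-D Euclidean geometries:
`spread-refs` places three references on a wide triangle dominating every
pool triple (pool points confined to a small central disc), so
spread-maximizing selection must recover them; `clumped-refs` confines the
references to a small disc inside a wide pool — the pathology the selection
scheme exists to avoid.  One candidate per category is planted with its role
exact by construction; the "between" candidate sits on an axis-aligned
midpoint whose coordinates are binary-exact, so its triangle deviation is
exactly 0.0 in floating point.

## Numerical conventions and degenerate inputs

- Gap character is `-` internally; `.` is normalized on read, sequences are
  uppercased.  Secondary-structure alphabet is strictly {H,E,C}.
- Column coordinates are 0-based half-open internally; human-facing reports
  are 1-based.
- Distance matrices must be symmetric within 1e-9 (then exactly
  symmetrized) with an exactly zero diagonal; the triangle inequality is not
  assumed.
- Undefined scores (zero reference pairs/columns) are NA, never 0.
- Objective ties in selection break lexicographically on sorted ids; rank
  ties in classification resolve toward the neighbourhood category;
  re-rooting ties (maximize) break by enumeration order.
- All randomness flows through explicit integer seeds (numpy Generator /
  `random.Random`); library-level calls never touch global RNG state.

## Problem sizes used in the checks

The re-rooting guarantee is exercised at the full published scale (200
random 1000-leaf trees, 3 references, threshold 900) — the search is
linear-time per candidate rooting and completes in seconds.  Oracle
equivalence checks run 500 random instances per operation at sizes where
exhaustive enumeration is the oracle (alignments ≤ 6×20, trees ≤ 12
leaves).  Corruption-rate calibration uses 3σ binomial bounds at ~7500
structure positions.

## Known limitations

- The exact re-rooting candidate order of the original procedure is not
  published; the seeded first-passing search is this package's documented
  interpretation, with `maximize` as a fully deterministic alternative.
- The original alignment-distance metric, MDS dimensionality and
  per-category quotas are likewise unpublished; percent identity, dim ≤ 3
  and equal round-robin quotas are package choices, isolated behind the
  module interfaces so they can be recalibrated.
- SSPA assumes total predictions; masking of low-confidence predictor
  output is not modelled.
- The toolkit scores and selects; it never runs aligners or structure
  predictors.
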