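# Methods

This note records the models, algorithmic conventions and numerical
choices behind `discophylo`, and what the simulation-based checks do
and do not establish.

## Tagging and duplication–loss parsimony rooting

A rooted, species-resolved gene tree is tagged bottom-up: an internal
node is a **duplication** iff the species sets of its two child
subtrees intersect, a **speciation** otherwise.  Tagging is a pure
function of topology and species labels.

Rooting an unrooted tree scores every edge as a candidate root
position and keeps the minimum of

    score = w_dup · D + w_loss · L,

where `D` is the number of duplication nodes and
`L = Σ_dup |A∖B| + |B∖A|` over duplication nodes with child species
sets `A`, `B`.  Defaults are `w_dup = w_loss = 1`.  The loss count is
this package's definition (each species present under one duplicate
but absent under the other implies one loss); it is species-tree-free
and monotone in the asymmetry of the two duplicates, and it is
isolated behind `tagging.duplication_losses` so an alternative scheme
can be swapped in.  Ties between equal-scoring rootings go to the
first minimizing edge in a deterministic post-order edge enumeration
started at the leaf with the lexicographically smallest gene label.
Scoring is recomputed per candidate root (O(n²) overall), which is
simple and exactly matches an all-rootings brute force; the tests
verify this against an independent dendropy-based scan.

## Decomposition (pruning, and pruning with regrafting)

The tagged tree is traversed in post-order.  At each duplication node
one child subtree is detached and emitted **untrimmed**; pruning
strategies are `larger` (detach the strictly larger child, ties detach
the right child), `smaller` (strictly smaller, ties right) and
`random` (seeded).  Sizes are the *current* subtree sizes, i.e. they
include any leaves regrafted below by earlier steps.  In regrafting
mode a separate copy of the detached subtree is trimmed down to the
species absent from the remaining backbone and reattached where the
duplication node stood (nothing is attached if no species remains; a
single remaining leaf is attached directly), after which degree-2
nodes are contracted.  Both modes emit exactly `D + 1` single-copy
trees; in regrafting mode the backbone carries every input species
exactly once, so no species can vanish from a decomposed collection.
Trimming and regrafting operate on copies so the emitted output is
never mutated afterwards.

## Quartets

Quartet topologies are kept canonical (pairs sorted, pair containing
the smallest label first).  Induced quartets are computed by path
disjointness on the four leaves; enumeration over all 4-subsets is the
deliberate Ω(n⁴) step — decomposition bounds the per-tree n by
min(leaves, taxa), which is the point of running it before quartet
generation.  GTF weights are raw integer counts; trees with fewer than
four leaves are skipped.  A quartet of four genes from four distinct
species is **speciation-driven** when every cross-pair LCA is tagged
speciation; the stricter "all cross-pair LCAs" reading (rather than
"some") is the one consistent with all classifications of the worked
single-duplication example, and the fixture tests pin it.

## WMQC solvers

The exact solver enumerates all (2n−5)!! unrooted topologies (guarded
to 4–9 taxa).  For each taxon count it caches, once, an
`(topologies × 4-subsets)` int8 matrix of induced arrangements built
from edge bipartitions, so each instance reduces to one vectorized
gather; ties go to the first maximum in the deterministic enumeration
order.  Scores are exact integers for integral weights.

The heuristic recursively bipartitions the taxon set.  Quartets with
exactly one taxon on the far side are projected onto a dummy taxon
standing for that side; quartets split 2–2 are counted satisfied
(pairs respected) or violated, 3–1 splits are deferred.  Subproblems
of ≤ 9 taxa choose the bipartition by an exhaustive scan over all
splits with both sides ≥ 2 (the overall procedure remains a greedy
top-down heuristic); larger subproblems run seeded
Fiduccia–Mattheyses passes — single-taxon moves by maximum gain, each
taxon locked after moving, best move prefix kept — with three
restarts.  A seeded random topology is scored as a baseline floor and
returned only if it strictly beats the heuristic tree, which
guarantees the star-baseline contract.  The exact solver, not the
heuristic, is the correctness anchor: on 200 frozen low-noise 8-taxon
instances the heuristic reproduces the exact topology in ≥ 90% of
cases, and it can never exceed the exact score.

Normalization: entries whose four species are not all spanned by the
scored tree are excluded from both numerator and denominator.  The
pipeline always spans the table's species, so there the denominator is
the total table weight.

## DLCoal simulator

Branch lengths are in **generations**; rates are per gene per
generation; `pop_size` is the constant haploid population size N (one
coalescent unit = N generations).  Rates quoted per year convert by
multiplying with a generation time, which is left to the caller.

*Locus tree (top-down):* along every lineage, duplications (rate λ+)
and losses (rate λ−) arrive as independent Poisson processes; a
duplication spawns a daughter locus which itself duplicates and dies
at the same rates.  Extinct lineages are pruned and degree-2 nodes
contracted (branch lengths add); a duplication survives as a
duplication node only when both the mother and the daughter side
persist, and the daughter side is recorded for the coalescent bound.
Fully extinct families raise an extinction error; dataset generation
redraws them and reports the count.

*Gene tree (bottom-up):* within each locus branch, k lineages coalesce
at rate k(k−1)/(2N).  At a duplication, the daughter locus must be a
single lineage at the duplication time; this bound is enforced by
rejection — the daughter subtree's coalescent history is redrawn until
the bound holds — which is exact whenever it terminates.  The retry
cap is 500 per duplication node; families whose histories make the
bound practically unsatisfiable (a recent duplication above a deep
daughter subtree) are redrawn at dataset level and counted separately
(`n_bound_failures`).  Datasets are therefore conditioned on family
survival and on bounded-coalescent sampling succeeding; at the
moderate rates used throughout, bound failures are ≲ 0.1% of draws.

All randomness flows from a single integer seed; a fixed seed gives
byte-identical newick output.

### What the simulations emulate, and what they do not

The generator produces *true* gene trees under GDL + ILS with constant
N and constant rates.  It does not model gene-tree estimation error
(sequence simulation and tree inference), rate variation across
branches or families, hemiplasy-aware duplication times, or varying
population sizes.  Passing tests therefore demonstrate correctness of
the algorithms and consistency under the generative model — not
robustness to estimation error in real data.

### Study conditions used by the checks

Chosen once, before running the checks, as representative "moderate"
regimes (N = 10⁴ throughout):

* **Consistency curve** — fixed 6-taxon ultrametric species tree with
  every internal branch 2 coalescent units; λ+ = λ− = 2×10⁻⁶ per
  generation (≈ 0.5 expected duplication events per family over the
  tree's total length, λN = 0.02 per coalescent unit); 20 replicates
  at each of 10, 50, 200 and 1000 genes; regrafting decomposition with
  exact WMQC.  Recovery of the true tree must be non-decreasing in
  gene count and 1.0 at 1000 genes.
* **Quartet-frequency inequality** — balanced 4-taxon tree, internal
  branches 1 coalescent unit, λ+ = λ− = 3×10⁻⁶; 10 000 families, one
  gene sampled uniformly per species in families containing all four.
* **ILS closed form** — asymmetric 4-taxon tree with internal branch
  T = 1 coalescent unit and λ+ = λ− = 0; 6000 families; the matching
  quartet frequency is compared with 1 − (2/3)e^(−T) within three
  binomial standard errors.
* **Heuristic/exact agreement** — 200 instances of 12 true gene trees
  on random 8-taxon coalescent species trees (depth scale 2N), no
  duplication or loss.

These sizes keep the full test suite and the acceptance script each
within a few minutes on one CPU while leaving the stochastic checks
well-powered (3-SE bands, 95% intervals).

## Numerical and degenerate-input conventions

* Polytomies in input newick are resolved to binary by a deterministic
  left-to-right caterpillar expansion at parse time; a root with three
  or more children marks the tree unrooted.
* Branch lengths are preserved through I/O but ignored by tagging,
  decomposition and quartet machinery (topology-only algorithms).
* Families reduced to a single copy pass through the pipeline
  untouched (they induce no quartets).
* RF comparison refuses mismatched leaf sets and polytomous trees
  rather than silently restricting; normalization is by 2(n−3).
* Gene labels must be unique within a tree; species mappings must
  cover every gene label, and the delimiter rule maps labels without
  the delimiter to themselves.

## Known limitations

* The exact WMQC solver is bounded at 9 taxa ((2n−5)!! growth; the
  9-taxon matrix build takes tens of seconds once per process).
* The heuristic's bipartition objective (satisfied − violated, 3–1
  splits deferred) is greedy top-down; no optimality guarantee exists
  above the exhaustive-split subproblem size.
* The duplication-loss loss count is a package-level convention (see
  above), not calibrated against any external tagger.
* Bounded-coalescent sampling by rejection conditions datasets as
  described; exact bounded-coalescent densities are out of scope.
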