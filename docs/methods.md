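# Methods

## Problem setting

A FISH assay reports, per cell, the copy number of each of `d` gene probes
(typically 4–8).  One patient sample reduces to `n` distinct *cell count
patterns* `(x_1, …, x_d) ∈ N^d` with multiplicities.  Under the rectilinear
(L1) metric, the distance between two patterns counts the single-gene
duplication and loss events separating them, so a minimum-weight tree
spanning the observed patterns — allowing unobserved *Steiner* patterns as
internal states — is a most-parsimonious model of tumor progression from a
single ancestor, conventionally the diploid pattern `(2, …, 2)`.  Three
related objects appear throughout:

- **MST(n, d)** — minimum spanning tree over observed patterns only.
- **RSMT(n, d)** — minimum-weight tree with optional Steiner nodes
  (NP-complete; both heuristics below approximate it).
- **MPT(n, d)** — minimum-weight unrooted binary tree with the observed
  patterns as leaves and `n − 2` internal nodes to be labeled.
- **DSMT(n, d)** — RSMT under a generalized metric that admits chromosomal
  and whole-genome doublings at unit cost.

## MST-based heuristic (`msttree`)

`RSMT(3, d)` is solved exactly by the coordinatewise median: probe counts
are independent, the integer median minimizes the sum of absolute
deviations, and the optimal star weight is `Σ_j (max_j − min_j)`.  The
heuristic starts from the L1 MST (Kruskal; ties broken by edge length,
then lexicographic endpoint patterns, so output is deterministic) and
repeatedly solves a median instance per (center, neighbor-pair) triplet of
the current tree.  Because insertion order changes the local optimum, the
candidate inserted is the one with positive *local gain* (weight of the
two replaced edges minus the 3-star weight) and minimum *inference score*
(sum of the triplet members' *Steiner counts*, where a node's Steiner
count is the number of triplets containing it whose median differs from
all three members).  Remaining ties fall to larger gain, then the
lexicographically smallest median.  After every insertion, Steiner nodes
of degree ≤ 2 lying on a shortest path between their neighbors are
spliced out so intermediate insertions cannot bloat the tree.  The weight
is a non-negative integer that strictly decreases with each insertion, so
termination is guaranteed; the loop stops when no candidate has positive
gain.

The scored triplet set is every (center, unordered neighbor pair)
combination in the current tree — this subsumes both the path and star
cases and keeps the candidate set `O(Σ deg²)`.  When a median coincides
with one of its own triplet's labels, the move degenerates to a rewiring
(the two replaced edges become two edges incident to that node) rather
than a node insertion.

## Parsimony engine and MPT search (`mpt_search`)

Copy numbers are ordered (additive/Wagner) characters, and the metric
separates over probes, so scoring a fixed leaf-labeled binary topology is
an exact per-probe interval DP (Farris intervals): a leaf carries
`[x, x]`; an internal node takes the intersection of its children's
intervals when non-empty at no cost, else the gap interval at a cost equal
to the gap length.  The total equals the minimum tree weight over all
integer labelings of internal nodes, and is invariant to the rooting used
by the DP (both facts are tested against exhaustive enumeration).  The
same combine rule run in both directions yields a *message* — interval
plus accumulated cost — for every directed edge; any edge, leaf insertion
point, or NNI rearrangement is then scorable in `O(d)`, and greedy
stepwise addition costs `O(n² d)` overall.

The topology search replaces the closed-source parsimony program used as a
black box in the original pipeline.  It is a standard random-addition +
hill-climbing scheme: `restarts` stepwise-addition trees (the first from
the input order, the rest from seeded shuffles), each refined by
steepest-descent NNI (SPR available by flag) until no neighbor improves.
One additional deterministic start is the MST-heuristic tree *binarized*
into a leaf-labeled topology (each tree node becomes a chain of binary
internal nodes, so the topology admits a labeling of exactly that tree's
weight).  This start anchors the search at a Wagner score no worse than
the MST-heuristic weight; pure random-addition NNI alone was measured to
stall 1–7 % above the optimum on 120–150-pattern samples, and seeding a
parsimony search with a good tree is common practice.  Defaults: 10
restarts, NNI, 200 hill-climb rounds maximum.

## From MPT to RSMT (`derive_rsmt`)

A scored MPT fixes only leaf labels.  Any weight-optimal internal labeling
followed by contraction of trivial (zero-length) edges yields an RSMT
candidate of identical weight; the freedom is in how many Steiner nodes
survive.  For each leaf the *lifting* test asks whether its pattern can
label its parent at no cost: remove the leaf, root at the former parent,
force the root label to the leaf's pattern and rescore.  Because each
child subtree's cost as a function of the root label is exactly
`W_c + dist(x, I_c)` (accumulated cost plus per-probe distance to the
child's Farris interval), the forced score is available in closed form.
Each liftable leaf generates a candidate: bottom-up ranges over the
remaining tree, top-down assignment (each internal node takes, per probe,
the value in its interval closest to its parent's value), contraction.
One *unrooted fallback* candidate roots at an internal node and picks the
root value in the root interval closest to the diploid pattern — any
interval point is weight-optimal, so the diploid bias is purely a
tie-break reflecting the healthy-ancestor convention.  The candidate with
the fewest Steiner nodes wins (weights are all equal by construction;
remaining ties go to the lexicographically first provenance).  Candidates
lift one leaf each; simultaneous multi-leaf lifting is not explored.

## Duplication events (`dsmttree`)

The generalized metric is defined by an explicit event grammar: on a
parent-to-child edge, first apply a set of doublings — at most one
whole-genome duplication and at most one duplication per chromosome, each
doubling the counts current when it applies (doubling operations commute,
so the set, not the order, matters) — then pay one unit per residual
single-gene gain or loss.  The grammar is minimized exhaustively (at most
`2^(c+1)` doubling sets for `c` chromosomes; probe panels are small), the
empty script is always a candidate, so the cost never exceeds L1 and ties
prefer no duplication.  Halving is not an event, so the metric is
directional; unrooted edge weights take the cheaper orientation.  Whether
multiple sequential whole-genome doublings, or single-gene events
interleaved between doublings, should be admitted is unknowable from the
available description; the grammar above is a declared approximation that
reproduces both worked event kinds (chromosomal and whole-genome).

The DSMT pipeline seeds from the generalized-metric spanning tree (or a
user-supplied tree), orients it away from the diploid (else minimum-sum)
pattern, flags every edge whose duplication script strictly beats its L1
length, removes those branches, re-solves each component with a chosen
RSMT heuristic (component inputs are its observed patterns plus the
removed-branch endpoint patterns, so endpoints always survive rebuilding),
and re-inserts the removed branches between the same endpoint patterns.
Finally the reassembled tree is compared, under the generalized metric,
with the plain RSMT-heuristic tree and the better one is returned — a
best-of-candidates step that guarantees duplication handling can only
help.

## Exact oracle (`exact_rsmt`)

Ground truth for small instances: Steiner points are restricted to the
Hanan grid (Cartesian product of the terminals' per-probe coordinate
values), on which the Dreyfus–Wagner subset DP finds the optimum;
shortest grid paths under L1 are the L1 distances themselves, so the
"walk" relaxation is one min-plus product with the distance matrix.  The
Hanan restriction follows the classical d-dimensional generalization and
is additionally regression-tested against an unrestricted bounding-box
brute force on tiny 2-probe instances rather than trusted on the theorem
alone.  Default limits (8 terminals, 5000 grid vertices) abort with a
diagnostic rather than silently approximate.

## Simulator (`grow_tree`)

The generator emulates the benchmark regime of the tumor-progression
literature: growth from a diploid root on panels of 4/6/8 probes, growth
factors 0.4/0.5, and 120–150 distinct patterns per sample.  The published
descriptions do not pin down the generative details, so the semantics here
are declared, not inferred: per round, every existing cell buds a daughter
with probability `g` (the *growth factor*); each new edge applies exactly
one event drawn from the event distribution (defaults: gain 0.5, loss 0.5;
chromosomal/whole-genome doublings off unless configured, in which case
the default panel layout pairs two probes per chromosome); counts stay
non-negative; with `zero_absorbing` (default on) a probe at zero never
re-amplifies, reflecting the irreversibility of homozygous loss.  Each
sample draws its own distinct-pattern target uniformly from the configured
range and stops the moment it is reached — single buds add at most one
distinct pattern, so the count lands exactly on target and varies across
samples over the whole range.  Multiplicities are the number of simulated
cells per pattern.  A sample that cannot reach its target (degenerate
all-zero states under loss-only settings) aborts at the node budget
(10⁶).

What the simulator does *not* emulate: FISH measurement noise, probe
dropout, cell death, or subsampling of the tumor.  A consequence worth
knowing: with only single-gene events, every intermediate pattern along
the lineage is emitted, samples are lattice-connected, the MST has all
edges of length 1 and is provably optimal (any spanning tree with `s`
Steiner nodes has `n − 1 + s` edges of length ≥ 1) — so on pure
single-gene simulations the heuristics tie at the optimum, the degenerate
case in which the RSMT is simply the MST.  Passing weight-ordering tests
on such samples certifies consistency, not Steiner inference; Steiner
inference is exercised by sparse random instances checked against the
exact oracle, and by duplication-enabled simulations whose doubling jumps
leave L1 gaps.

## Numerical and design choices

- All tree weights and distances are exact integers; no floating point
  enters any objective.
- Multiplicities never weight an objective — the formal problems are over
  distinct patterns — and are carried only for reporting.
- Determinism: MST ties, insertion ties, candidate ties and contraction
  survivor choice are all resolved lexicographically; all search
  randomness flows from explicit seeds.
- Trivial-edge contraction keeps the observed endpoint (smallest id among
  observed) so observed identities survive merges.
- Problem sizes in the test suite and acceptance script: exhaustive
  cross-checks use ≤ 6–8 terminals with counts ≤ 6–10 (where enumeration
  is exact and fast); full-scale weight-ordering runs use the native
  120–150-pattern regime with 2 search restarts; duplication simulations
  use 30–50-pattern samples.  These sizes are the package's scaled study
  conditions for desk-scale reproduction; the published head-to-head
  tables against the original third-party binaries and patient datasets
  are out of scope.

## Known limitations

- The parsimony search is NNI-centric; instances with many equal-weight
  optima may return any one of them (enumerating co-optimal RSMTs is an
  open problem).
- The duplication grammar is an approximation of the generalized metric it
  stands in for; scripts with repeated whole-genome doublings on one edge
  are not considered.
- The exact oracle scales to a handful of terminals only, by design.
- `can_lift` tests one leaf at a time; candidate sets from simultaneous
  lifts are not enumerated.
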