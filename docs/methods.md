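# Methods

This note documents the models and procedures implemented in `phatpack`,
their assumptions, the tunable parameters, and the design choices made
where the problem left genuine freedom.

## Sequence entropy (module `entropy_consensus`)

For an aligned set *s* of sequences over the five states
`c ∈ {A, C, G, T, −}`, the per-site entropy is

    H_i = − Σ_c f_c,i · log₂ f_c,i      [bits]

with `f_c,i` the frequency of state *c* at site *i*, `0·log₂0 = 0`, and the
total entropy `H(s) = Σ_i H_i`.  Gaps are a regular fifth state: sites
dominated by gaps then contribute little, mirroring the fact that standard
likelihood models treat gaps as undetermined states that contribute nothing
to the placement signal.  Ambiguity codes are mapped to gaps during
alignment normalization (`io_formats.read_alignment`): fractional counting
of ambiguities is possible in principle but deliberately not implemented —
in large rRNA databases their share of non-gap characters is negligible.

`H_i` ranges over `[0, log₂ 5 ≈ 2.32]`; it is 0 exactly for single-state
sites and maximal when all five states occur at 20% each (verified in the
test suite by a grid-search oracle over the frequency simplex).  A
*normalized* entropy `H(s) / (L · log₂ 5) ∈ [0, 1]` is provided for
reporting only; no algorithm depends on the normalization, which is this
package's own bounded-definition choice.

**Degenerate inputs.**  Empty sequence sets are a `ValueError` for
`set_entropy`; a taxonomic clade whose subtree holds no sequences gets
entropy 0 with a logged warning — such a clade can never be the
most-diverse candidate worth expanding, so this choice is inert.

## Consensus sequences

Three per-site methods, all over the 5-state alphabet:

* `majority` (default): the plurality state;
* `cavener`: the top state if its frequency exceeds 0.5, else a gap.  The
  classical rule's second branch (top two states jointly > 75%, each > 25%)
  would emit a two-base ambiguity code, which a 5-letter alphabet cannot
  express; the rule therefore collapses to gap in that branch.  This
  collapsed reading is this package's documented interpretation;
* `threshold(x)`: the top state if its frequency ≥ `x` (default 0.5), else
  a gap.

Ties prefer a non-gap state over the gap, then alphabetical order
A < C < G < T — deterministic, and biased toward retaining sequence signal
rather than erasing it.  `build_reference_set` additionally offers
`method="first"` (represent a clade by its lexicographically first actual
sequence), a deliberately simple alternative for comparing consensus-based
against sequence-picking reference sets; it is not tuned further.

## Taxonomy expansion (module `phat`)

Greedy loop: initialize the candidate list with the top-rank clades; while
the candidate count is below the target, remove the candidate with maximal
`H(t)` (over all sequences in the clade's subtree) and insert its immediate
sub-clades, updating the count by `−1 + #sub-clades`.  Choices the loop
specification leaves open, resolved here:

* **Leaf candidates.**  A clade without sub-clades cannot be expanded.
  Removing it would silently lose taxa, so leaves are retained as
  candidates and skipped by the argmax; the loop terminates when all
  candidates are leaves, even if the target is unmet.
* **Ties.**  Candidates with equal entropy are expanded in lexicographic
  order of their full taxopath, making runs exactly reproducible.
* **Overshoot.**  The final count may exceed the target when the last
  expansion adds many sub-clades; `CandidateSet.deviation_percent` reports
  the relative deviation.
* **Empty clades.**  Sub-clades without sequences still count toward the
  candidate total during expansion (they are taxa of the taxonomy) and are
  dropped with a warning at consensus time.
* **Memoization.**  A clade's sequence set never changes during expansion,
  so entropies are cached per clade; the test suite checks equivalence with
  a from-scratch greedy oracle that recomputes every entropy each round.

The constraint tree mirrors the taxonomy restricted to the candidate
paths (unary chains collapsed, no branch lengths) and is intended as a
monophyly constraint for the external ML inference.  Tip labels are the
sanitized full taxopaths (unsafe newick characters → `_`), with a mapping
table written alongside.

## Multilevel placement (module `multilevel`)

`CladeAssociation` maps every backbone edge to a clade-tree label or
`INNER`.  Routing modes:

* `best_hit` (default): a pquery follows its single highest-LWR placement.
  This matches how first-level accuracy is naturally scored (most-likely
  placement into the right clade) and makes routed+filtered an exact
  partition of the input.
* `mass_threshold(x)` (default `x = 0.5`): a pquery goes to *every* label
  whose accumulated LWR over its associated edges reaches `x`, so a query
  may enter several clade trees; queries reaching no label are filtered.

Both are provided because multi-placement handling at the first level is a
genuine policy choice; the default is `best_hit`.  Monophyly of a label's
edge set is checked by testing whether it equals `{e} ∪ edges-below-e` for
some edge `e` (the witness); this is the unique single-split reading under
which a full subtree and a single terminal edge are both monophyletic.

The analytic cost model assumes placement cost linear in the number of
reference taxa and one backbone plus one clade-tree placement per query:
`speedup = n_full / (n_bt + n_ct)`, `memory_factor = n_full / max(n_bt,
n_ct)`.  More than two levels are obtained by composing the tool, not by a
special case.

## Preprocessing (module `preprocess`)

Deduplication is *exact*: reads are uppercased (no U→T here — raw reads
are hashed as sequenced) and identical strings collapse across all
samples.  No fuzzy/OTU-style clustering is attempted.  Unique IDs are a
zero-padded running index in first-occurrence order, so output is
deterministic for a fixed input order.  FASTQ qualities are discarded —
placement is sequence-only.  Chunks all have exactly `chunk_size` records
except the last (default 50 000, the recommended lower bound for real
pipelines; tests use tiny chunks).  `resolve` checks that all chunk results
share one reference tree (topology + edge numbering), rejects IDs placed
in two chunks, reports never-placed IDs as unplaced, and emits per-sample
documents whose pquery multiplicities are the abundance counts — the test
suite verifies end-to-end conservation of the input read multiset.

## Evaluation (module `evaluation`)

The *expected edge* of a labelled query is the terminal branch of the
consensus tip whose taxopath is the longest prefix of the query's taxopath;
queries with no matching candidate are counted as unmapped and excluded
from statistics.  Distances:

* topological: shortest path in the edge-adjacency graph (edges sharing a
  node are adjacent); same edge = 0, adjacent = 1;
* branch-length: from the placement attachment point (distal length,
  measured from the child-side node per the jplace convention) to the
  nearest point of the expected edge — any position on the expected edge
  scores 0, consistent with treating on-branch placements as exact hits.
  Pendant lengths are off-tree and excluded from all distances.

Per query, both distances are LWR-weighted means over its placements.
EDPL is `Σ_i Σ_j p_i p_j d(att_i, att_j)` over ordered pairs with LWRs
normalized to their sum.  Clade-identification accuracy is best-hit label
equality (any edge carrying the right label counts, so overlapping
associations are handled), multiplicity-weighted.  Taxonomic assignment
accumulates LWR onto every taxopath prefix of each placed edge (internal
edges carry the longest common prefix of their descendant tips) and
assigns the deepest prefix reaching the threshold, default 0.66 — a
configurable choice in the spirit of established placement-based
assignment tools; queries reaching no depth are assigned at the root.

## Synthetic data (module `fixtures`)

The generators emulate the *shape* of a taxonomically annotated reference
database: a complete b-ary taxonomy (default depth 3, branching 3, 6
sequences per leaf clade, 200 alignment columns) whose sequences diverge
hierarchically — each clade mutates its parent's ancestral sequence
per-site at the clade's divergence rate (default 0.05; planted "diverse"
top clades use 0.5), substitutions uniform among the other three bases,
plus a global 10% of all-gap columns.  Read samples draw with replacement
from a shared unique-read pool sized by the duplicate rate (default 0.5).
Mock placement documents plant each query on its true edge and all edges
within a topological noise radius, with Dirichlet-drawn LWRs sorted so the
true edge always carries the largest weight, and distal lengths uniform on
the edge.  `make_reference_tree` decorates the constraint topology with
random branch lengths as a stand-in for ML inference.

These choices are the simplest that drive the algorithms' decision points
(entropy ordering, routing, distance recovery).  What they do *not*
emulate: realistic rRNA evolution (no indels, no rate heterogeneity, no
back-substitution structure), taxonomies with uneven breadth/depth,
sequencing error, chimeras, or placement-engine likelihood behaviour.
Passing tests therefore demonstrate algorithmic correctness and internal
consistency, not expected accuracy on empirical databases.

## Numerical and scale choices

Frequency vectors must sum to 1 within 1e−6; LWR sums may exceed 1 by at
most 1e−6; distal lengths may exceed the branch length by at most 1e−6 and
are clamped for geometry.  Float branch lengths round-trip through newick
at `%.10g`, with semantic (tolerance-based) document comparison rather
than byte equality.  Test problem sizes are deliberately small — toy
taxonomies ≤ 50 clades for the greedy-oracle equivalence, exhaustive
edge-pair checks on random trees up to 12 tips, synthetic pipelines with a
few dozen queries — chosen so the whole suite completes in about a minute
while still exercising every code path; all generators are seeded and the
hypothesis profile is derandomized.

## Known limitations

* No ML inference or placement engine is invoked; the pipeline's accuracy
  statements are about the surrounding machinery, with synthetic stand-ins
  for both engines.
* The taxonomy is positional: no named-rank semantics, no support for
  merging or mapping between taxonomies.
* jplace support targets version 3; version fields other than 3 are
  rejected rather than coerced.
* Amino-acid alphabets are unsupported throughout (5-state nucleotide
  alphabet only).
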