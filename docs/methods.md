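# Methods

## Problem and model

Taxonomic assignment of a DNA barcode query against a reference database is
done here entirely by pairwise local-alignment similarity. Every method has
the same two-stage shape: retrieve a set of reference sequences for the
query, then report the lowest common ancestor (LCA) of their lineages over
the six ranks phylum/division, class, order, family, genus, species.
Raw alignment score is the (order-reversing) stand-in for genetic distance
throughout: a larger score is a smaller distance, so "nearest" means
"highest raw score" and all threshold comparisons are written on scores.

### Retrieval rules

* **k-NN** — the k top-scoring hits; tie groups at the k boundary are kept
  whole, so the retrieved set is permutation-invariant. k = 1 is the
  classical best-hit method.
* **n%-NN / n%-k-NN** — hits with percent identity ≥ n, optionally capped
  at the k best by raw score (again keeping tie groups whole).
* **NNCauto** — with A the set of tied nearest neighbors of the query Q and
  s(Q,A) their score: for each a ∈ A, the borderline set B_a holds the
  top-scoring hits of a among those with s(a,·) **strictly below** s(Q,A);
  the neighborhood of a is every hit of a scoring at least s(a,B_a). The
  LCA is taken over the union of all A, B_a and neighborhoods. Sequences
  tied with Q's score are additional nearest neighbors, not borderline
  candidates — hence the strict inequality.
* **QCauto** — borderlines are found exactly as in NNCauto, but the radius
  is centred on the query: among all borderline candidates, the one closest
  to Q (highest s(Q,b), ties broken by id) sets the threshold s(Q,B), and
  every hit of Q scoring at least that much enters the LCA together with A
  and the selected borderline.

Both auto methods satisfy, by construction, the criterion that the distance
from the query to its assigned taxon never exceeds the maximum
within-neighborhood distance used in the LCA; in score terms,
s(A,B) < s(Q,A) for NNCauto and s(Q,B) ≤ s(Q,A) for QCauto, which the test
suite asserts on every trace.

**Degenerate case — no borderline.** If the database is exhausted within
the query's radius (e.g. a single-record database), the borderline does not
exist and the criterion is unevaluable; both auto methods then return
"unidentified" at every rank. This is the conservative choice and matches
the character of the query-centric method. Self-hits are never excluded:
with the query's own record in the database, A may be that record, which is
exactly the intended "known species" behaviour.

**QCauto's LCA set.** When several borderline candidates exist, the set
entering the LCA is N ∪ A ∪ {selected borderline}. A candidate that was not
selected can lie outside the query's radius and is then deliberately left
out; candidates at the threshold score are inside N anyway.

### LCA variants

The strict LCA walks the ranks top-down, assigning a rank when all lineages
with information there carry one name. Missing ranks are wildcards: they
neither support nor contradict (reference taxonomies have gaps). The first
rank with two or more names is a conflict, and that rank and everything
below it stay unassigned — conflict truncation is hierarchical. A rank at
which *no* lineage has information is left unassigned without stopping the
descent, so a gap in every input lineage can propagate to the output.

The relaxed LCA tolerates a bounded minority of conflicting lineages: at
each rank, a taxon carried by at least `min_support` of the lineages
non-missing there is accepted, and the working set is restricted to its
carriers (plus lineages missing at the rank) before descending.
`min_support` must exceed 0.5, which makes the qualifying taxon unique; the
default of 1.0 reproduces the strict behaviour. The appropriate degree of
relaxation is database-dependent and left to the user.

### Scoring scheme

The aligner is an exact affine-gap Smith–Waterman (no heuristic seeding —
the auto methods need the *complete* set of references above a score, and
desk-scale databases make exhaustive O(N·L²) search acceptable). Defaults:
match +1, mismatch −2, gap open −5, gap extend −2 (a gap of length g costs
open + (g−1)·extend), admission threshold `min_score` 20. These magnitudes
are conventional for nucleotide search; only the score *order* drives the
assignment methods, so the exact values matter little as long as they are
sensible. Positions involving N always score as mismatches, and a column is
counted identical only when both residues are equal and neither is N.
Ambiguity codes other than N are collapsed to N on input so the scorer
faces a clean two-class decision.

Numerical determinism: hits are ordered by raw score descending then
subject id ascending (a total order); truncation never splits a tie group.
The traceback reporting identity and length prefers diagonal over vertical
over horizontal moves, and among equal-score end cells picks the longest
alignment, then the smallest (row, column). The empty alignment scores 0,
so raw scores are never negative. The dynamic program is verified against a
brute-force oracle (max over all substring pairs of an independent
recursive global affine aligner) on short random sequences.

The engine is a pluggable contract: the exact aligner (with a pair cache
shared across a benchmark run) or a score-table aligner used to express
method tests directly as score matrices.

## Benchmark protocol

Queries are sampled per taxonomic group — up to a limit of genera per group
(order or phylum/division), then one sequence per sampled genus — and may
be reduced to a random contiguous window ("mini-barcode", 200 nt by
convention; sequences not longer than the window are used whole, since the
protocol does not address shorter queries). The window offset is keyed on
(seed, query id) so every method sees identical inputs within a run.

Two settings: **no-LOOCV** keeps the query's record in the database
(species covered by the database) and **LOOCV** removes exactly that one
record by id — conspecific and congeneric records remain, which is what
makes misidentification patterns interpretable.

Outcomes per query: the **correctness index** (number of ranks assigned and
matching the truth, 0–6) and the **incorrectness index** (ranks assigned
and wrong, 0–6); the two plus the number of unassigned ranks always sum
to 6. Per rank, the outcome is one of four categories: correct, incorrect,
unidentified-with-a-misassigned-higher-rank, or cleanly unidentified.
Queries are required to have fully populated truth lineages (they are
selected to have genus and species information).

## Synthetic reference databases

The generator grows a balanced taxonomy (a configurable number of children
per rank; names are dotted paths so sibling groups never share names) and
evolves sequences down it star-fashion: each child's sequence is its
parent's with a fixed proportion of sites substituted. Sites are drawn
without replacement per branch — making expected pairwise identity
analytically checkable — and each substituted site receives a uniformly
chosen different base. No indels, no rate heterogeneity, no back-mutation
along a single branch.

Defaults (two children per rank → 64 species, one record per species,
150 nt, per-rank branch divergences 0.12/0.10/0.08/0.06/0.04/0.02 from
phylum to species, within-species 0.005): ranks are then strongly separated
in score space, which is the regime the correctness properties are stated
in. What the model does *not* emulate: alignment-length variation (ITS-like
loci), misannotated references, uneven taxon sampling, and paraphyly —
passing tests on these fixtures demonstrate algorithmic correctness and the
methods' relative conservativeness, not empirical accuracy on public
databases.

On that fixture the benchmark reproduces the methods' qualitative contrast
(problem sizes: 64 references, 20 queries, full-length): with the query in
the database, 1-NN is perfect; with it removed, 1-NN misassigns the species
of every query while NNCauto and QCauto stop at a defensible higher rank
and misassign nothing. With one record per species, QCauto can never
assign the species rank under LOOCV — its nearest neighbor and borderline
are necessarily different species — which the suite checks both as a
structural property and on the fixture.

## Design choices and limitations

* The borderline "farther than Q" comparison is strict; score ties with Q
  count as additional nearest neighbors (see above).
* NNCauto's step-II and step-III searches share one database search per
  nearest neighbor; QCauto needs an extra query-centred pass, which is why
  it is the slower of the two.
* LOOCV removes only the query's own record, never its species.
* One global seed drives each randomised step through purpose-keyed
  substreams (query selection, window offsets), so runs are bit-reproducible.
* Out of scope: external search engines and their E-values, composition- or
  tree-based classifiers, global-alignment similarity, taxdump ingestion,
  ranks beyond the six evaluated levels.
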