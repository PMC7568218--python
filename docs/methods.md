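# Methods

## Problem and data model

The package operates on a multi-source disease knowledge graph held in
flat tables. Nodes are disease concepts; each belongs to one source
namespace (its CURIE prefix) and may carry a set of cross-reference
CURIEs (`xrefs`) into other resources — the curated equivalence
mappings. Edges are classification (`subClassOf`, child → parent,
scoped to one ontology source), phenotype annotation
(`has_phenotype`), and gene association (`associated_with_gene`).
Phenotype and gene objects are annotation endpoints and need not be
nodes; disease endpoints must resolve, and each source's
classification must be acyclic (a node may have several parents — the
classification is a DAG, not a strict tree).

All identifiers are normalized on ingest: prefixes uppercased, the
long Orphanet dialect collapsed to the short canonical form (`ORPHA`,
which is accepted and emitted; `ORPHANET` accepted only). Prefix
matching downstream is by canonical equality, never by regular
expression, so dialect spelling can never split one concept into two
fingerprint dimensions. Local ids are opaque strings; no checksum or
range validation is attempted.

## Route 1: mapping-fingerprint similarity

Eligible diseases are those of the primary namespace with at least one
xref into the mapping namespaces (default `ORPHA`, `OMIM`, `UMLS`);
the rest are excluded, since an all-zero vector has no defined cosine.
The *mapping universe* is the lexicographically sorted set of distinct
normalized xref CURIEs over eligible diseases, pooled across all three
namespaces — a mapping carried by many diseases is one dimension. Each
disease's fingerprint is its indicator vector over the universe,
stored sparsely as a bit-index set.

Binary cosine similarity is computed in set form,
`|A∩B| / sqrt(|A|·|B|)`, which equals the dense dot-product-over-norms
form exactly (a property test asserts this against a numpy oracle).
Identity of non-empty bit sets returns exactly 1.0 and disjointness
exactly 0.0, so bin membership at the extremes is never subject to
floating-point noise. Pair enumeration uses an inverted index from
mapping to carrying diseases, touching only co-occurring pairs; it is
provably equivalent to the exhaustive n(n−1)/2 double loop (tested
against one on ≤50-node graphs). Scores are kept at full precision;
two-decimal rendering exists only in the output table (`score_2dp`),
so threshold and bin boundaries at 0.5 / 0.7 / 1.0 are exact.

Score bins: the reporting layout is {score = 1}, {0.5 ≤ s < 1},
{0 < s < 0.5}; the review cross-tabulation layout splits the upper
region at 0.7 ({0.7 ≤ s ≤ 1}, {0.5 ≤ s < 0.7}, {s < 0.5}). Bin
specifications are validated to partition (0, 1] — overlaps and gaps
are configuration errors.

## Route 2: classification-tree sibling derivation

Three steps per ontology tree: (1) map primary diseases into the tree
through their xrefs whose prefix matches the tree source (xrefs whose
targets are absent from the tree are ignored); (2) collect the
siblings — classes sharing at least one *direct* parent — of every
mapped class; (3) map siblings back to primary diseases. The traversal
is exactly one hop up and one hop down; descendant closure would
compute a subtype (parent–child) relation, which is a different,
deliberately out-of-scope derivation. No ontology-level filtering
(e.g. by Orphanet classification level) is applied.

Design choices made where the procedure was genuinely open:

* **Multi-mapping fan-out.** A disease mapped to several ontology
  classes contributes the union of all their sibling sets.
* **Co-mapping is not siblinghood.** Two primary diseases mapped to
  the *same* class are duplicate candidates for the fingerprint route,
  not sibling pairs; the tree route never emits them.
* **Pairs are unique.** A pair derivable through both trees or several
  parents is emitted once; provenance (routes, via-parents) is kept on
  the pair.

Candidates are then annotated with shared phenotype terms and shared
genes (plain set intersections of the two members' annotation sets)
and filtered: keep pairs with ≥ `min_phen` shared phenotypes and
≥ `min_gene` shared genes (default 1 and 1). Survivors are typed
`Siblings`. Ranking is by shared-gene count descending, then
shared-phenotype count, then canonical pair order. Genes rank first
because gene overlap is the much scarcer, hence more specific, signal
in annotation data; the threshold filter itself is unaffected by this
ordering choice.

## Evaluation

Curated labels per pair: `Duplicated`, `Siblings`, `Subtypes`
(similar), `Unrelated` (not similar), `Ungrouped` (undecidable —
excluded from every metric denominator, permanently). Classification
is score ≥ threshold, with the boundary inclusive (a 0.5-scoring pair
is predicted similar). Precision = TP/(TP+FP), recall = TP/(TP+FN),
F = harmonic mean; a zero denominator yields an undefined metric
(`None`), never 0. Whole-percent rounding is display-only.
`records_from_counts` replays a published (label × bin) count table
through the same code path by assigning each count its bin's midpoint
score. Retirement (a disease no longer qualifying as rare under the
fewer-than-200,000-affected US definition) is a record-level flag in
the label table: pairs touching a retired disease are dropped before
evaluation.

Combining the two routes is plain set arithmetic over canonical pairs
(members sorted lexicographically), with |A∪B| = |A|+|B|−|A∩B| holding
by construction and a cross-tabulation of the two routes' type
assignments over the overlap.

## Synthetic-data generator

The generator emulates the statistical structure of a real
rare-disease knowledge graph at desk scale:

* **Coverage.** Per-source xref coverage defaults to
  {ORPHA 0.45, OMIM 0.52, UMLS 0.53} with probability 0.22 of a
  background disease carrying no xref at all — scaled from the
  observed shape of real mapping data, where roughly half the diseases
  map to any given resource and about a fifth map to none and must be
  excluded.
* **Planted duplicates** copy the partner's xref set exactly (forced
  non-empty), so their cosine is exactly 1.
* **Planted subtypes** share all but one xref (leader forced to ≥2
  xrefs; the partner drops one and gains a fresh one), the smallest
  perturbation that keeps the score high but below 1 — with k leader
  xrefs the score is (k−1)/k ∈ [0.5, 1).
* **Planted sibling families** (default 4 families of 4) get, per
  tree, one synthetic parent class with one child class per member,
  back-mapped via a member xref; members share no mappings, so only
  the tree route can find them. Each member carries a family-level
  phenotype and gene with probability √p, so a sibling pair shares
  one with probability ≈ p (defaults p = 1, making the
  phenotype-and-gene filter deterministic for planted families).
* **Collisions** (default off) plant unrelated background pairs
  sharing one mapping — the fingerprint route's false-positive mode.
* **Label noise** corrupts each emitted curation label to a different
  random label with the given probability.

One integer seed drives everything through sub-streams spawned from a
single `SeedSequence` (separate streams for xrefs, annotations,
labels, collisions), so adding draws to one component never reshuffles
another, and identical configs produce byte-identical fixture files.
Identifier uniqueness comes from deterministic counters in disjoint
numeric ranges, not from random draws.

Default problem size is 60 diseases with 5 duplicate pairs, 5 subtype
pairs and 4 families of 4 — large enough that every route, filter and
metric is exercised with non-trivial counts, small enough that the
whole suite (including a brute-force pair-enumeration oracle and a
20-seed noise-degradation sweep) runs in well under a minute.

What passing tests do and do not show: the generator reproduces the
*combinatorial* structure (coverage gaps, planted pair geometry, tree
shape, annotation overlap) but not realistic nomenclature, correlated
mapping errors across resources, prevalence, or the long-tailed
annotation-density distributions of real ontologies. Noise-free
recovery of planted types therefore validates the machinery, not
real-data accuracy — on real graphs the score-based type assignment is
a pre-sort for expert review, whose judgments (as the planted
Unrelated collision pairs illustrate) can overrule a perfect score.

## Numerical and degenerate-input choices

* Threshold comparisons are ≥ (inclusive) at 0.5; bins validated to
  partition (0, 1].
* Ties in every ranking and report are broken by canonical pair order,
  making all outputs permutation-invariant and re-runs byte-identical.
* Fewer than two eligible diseases, an empty universe, an all-zero
  fingerprint, an all-`Ungrouped` label set, a cyclic classification
  and an unresolvable edge endpoint are all explicit errors, not
  silent empties; an empty tree-mapping result is a logged warning
  (legitimately possible on sparse data).

## Known limitations

Sibling derivation ignores classification levels (a "group of
disorders" parent yields very broad sibling sets on real ontologies).
Subtype (parent–child) derivation, semantic phenotype similarity,
alternative similarity measures (Jaccard, TF–IDF weighting) and
additional gene sources are out of scope. Full-scale counts from the
real integrated graph require that data and are not reproduced here.
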