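# phenolink

Rare-disease resources (a national rare-disease registry, Orphanet,
OMIM, UMLS, MONDO, HPO, ...) each define disease concepts on their own
terms, so the same clinical entity can appear several times within and
across resources. `phenolink` identifies **phenotypically similar pairs
of diseases** in a primary rare-disease namespace from a multi-source
knowledge graph, to support harmonizing those records — merging
duplicates, regrouping siblings and subtypes, and flagging unrelated
records that merely look alike.

It implements two complementary identification routes over a knowledge
graph loaded from flat node/edge tables:

1. **Mapping-fingerprint similarity.** Each disease's curated
   cross-references into three mapping namespaces (Orphanet, OMIM,
   UMLS) are pooled into a *mapping universe* of distinct CURIEs; each
   disease becomes a binary presence vector over that universe, and
   pairs are scored by binary cosine similarity

   *cos(a, b) = |A ∩ B| / √(|A|·|B|)*

   where A and B are the diseases' mapping sets. Identical non-empty
   sets score exactly 1 (candidate duplicates); high partial overlap
   suggests subtype relationships; pairs sharing no mapping are
   dropped.

2. **Classification-tree sibling derivation.** Diseases are mapped via
   their xrefs into ontology classification trees (MONDO-like and
   Orphanet-like), the *siblings* of each mapped class (classes sharing
   a direct parent) are collected, and the siblings are mapped back to
   the primary namespace. Candidates are then prioritized by
   independent clinical evidence — pairs sharing at least one phenotype
   term **and** one disease gene are kept and typed "Siblings".

The two pair sets are combined with inclusion–exclusion accounting.
An evaluation module scores predictions against curated review labels
(`Duplicated` / `Siblings` / `Subtypes` / `Unrelated` / `Ungrouped`,
the last excluded from metric denominators) by precision, recall and F
measure at a score threshold (default 0.5, boundary inclusive).
Because real disease knowledge graphs are hosted in graph databases
and not redistributable, a seeded synthetic-graph generator with
planted duplicate pairs, subtype pairs, sibling families and optional
mapping collisions makes every stage testable offline.

## Worked example

Generate a synthetic fixture (60 diseases; 5 planted duplicate pairs,
5 subtype pairs, 4 sibling families of 4) and run both routes:

```
phenolink simulate --seed 7 --n-diseases 60 --out fx
phenolink map-similarity --nodes fx/nodes.tsv --edges fx/edges.tsv --out run
phenolink tree-siblings  --nodes fx/nodes.tsv --edges fx/edges.tsv --out run
phenolink prioritize --nodes fx/nodes.tsv --edges fx/edges.tsv \
    --pairs run/tree_pairs.tsv --out run
phenolink evaluate --pairs run/pairs.tsv --labels fx/labels.tsv --out run
phenolink report --pairs run/pairs.tsv --labels fx/labels.tsv \
    --prioritized run/prioritized.tsv --out run
```

`run/bins.json` — the score-bin summary of the fingerprint route:

```json
{
  "0 < similarity < 0.5": 0,
  "0.5 <= similarity < 1": 5,
  "similarity = 1": 5
}
```

The 5 score-1.0 pairs are the planted duplicates (identical mapping
sets); the 5 pairs in [0.5, 1) are the planted subtypes (all-but-one
mapping shared). `run/metrics.json` evaluates the scored pairs against
the fixture's curation labels:

```json
{
  "tp": 10, "fp": 0, "fn": 0, "tn": 0,
  "precision": 1.0, "recall": 1.0, "f_measure": 1.0,
  "threshold": 0.5, "n_excluded_ungrouped": 0
}
```

With no label noise every scored pair is correctly classified.
`run/report.json` combines the two routes:

```json
{
  "n_a": 10, "n_b": 24, "n_overlap": 0, "n_union": 34,
  "overlap_types": {}
}
```

Set A (10 pairs) is the fingerprint route, set B (24 pairs = 4 families
× C(4,2)) is the tree route after the shared-phenotype-and-gene filter;
the planted structure makes them disjoint, and the union obeys
|A ∪ B| = |A| + |B| − |A ∩ B|.

See `docs/methods.md` for the model, parameter and design details.

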