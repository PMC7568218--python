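"""End-to-end orchestration of the two identification approaches.

Approach A (mapping analysis): fingerprint every eligible primary
disease over the pooled cross-reference universe, score all pairs by
binary cosine, keep scores above a threshold, and type them from the
score alone — an identical fingerprint is read as a duplicate record,
a high partial overlap as a subtype relationship. (In production use
these automatic types are a pre-sort for expert review; against
synthetic graphs they are compared to the planted truth directly.)

Approach B (classification derivation): derive candidate pairs through
the ontology trees' sibling structure, then keep pairs sharing at least
one phenotype and one gene. Survivors are typed "Siblings".

The combined result is the union of both pair sets with
inclusion-exclusion accounting and a cross-tabulation of the type
assignments over the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .evaluate import UnionReport, union_report
from .fingerprints import SimilarityRecord, enumerate_similar_pairs
from .kg import KnowledgeGraph
from .pairs import DiseasePair, PairProvenance
from .prioritize import AnnotatedPair, prioritize_pairs
from .siblings import combine_pair_sets, derive_similar_via_tree, pairs_from_derivations
from .simulate import PRIMARY_SOURCE, TREE_SOURCES, XREF_PREFIXES


def classify_by_score(
    records: Iterable[SimilarityRecord], threshold: float = 0.5
) -> dict[DiseasePair, str]:
    """Score-based type assignment: 1.0 means identical mapping sets
    (duplicate records); at or above the threshold but below 1 means a
    high partial overlap (subtype-like). Sub-threshold pairs are not
    asserted similar and are dropped."""
    out: dict[DiseasePair, str] = {}
    for rec in records:
        if rec.score == 1.0:
            out[rec.pair] = "Duplicated"
        elif rec.score >= threshold:
            out[rec.pair] = "Subtypes"
    return out


@dataclass
class PipelineResult:
    """Artifacts of one full two-approach run."""

    records: list[SimilarityRecord]
    mapping_pairs: dict[DiseasePair, str]
    tree_candidates: dict[DiseasePair, PairProvenance]
    prioritized: list[AnnotatedPair]
    tree_pairs: dict[DiseasePair, str] = field(default_factory=dict)
    union: UnionReport | None = None

    def combined_types(self) -> dict[DiseasePair, str]:
        """Pair types over the union; where both approaches assign a
        type, the mapping-analysis assignment wins (it reflects the
        reviewed score evidence)."""
        combined = dict(self.tree_pairs)
        combined.update(self.mapping_pairs)
        return combined


def run_pipeline(
    graph: KnowledgeGraph,
    primary_source: str = PRIMARY_SOURCE,
    prefixes: Sequence[str] = XREF_PREFIXES,
    tree_sources: Sequence[str] = TREE_SOURCES,
    threshold: float = 0.5,
    min_phen: int = 1,
    min_gene: int = 1,
) -> PipelineResult:
    """Run both approaches on one graph and combine their results."""
    records = enumerate_similar_pairs(graph, primary_source, prefixes)
    mapping_pairs = classify_by_score(records, threshold=threshold)

    derivations = []
    for tree in tree_sources:
        derivations.extend(derive_similar_via_tree(graph, primary_source, tree))
    tree_candidates = combine_pair_sets(pairs_from_derivations(derivations))
    prioritized = prioritize_pairs(
        tree_candidates.keys(), graph, min_phen=min_phen, min_gene=min_gene
    )
    tree_pairs = {a.pair: a.assigned_type or "Siblings" for a in prioritized}

    return PipelineResult(
        records=records,
        mapping_pairs=mapping_pairs,
        tree_candidates=tree_candidates,
        prioritized=prioritized,
        tree_pairs=tree_pairs,
        union=union_report(mapping_pairs, tree_pairs),
    )
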