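"""Phenotype/gene prioritization of candidate disease pairs.

Tree-derived candidate pairs are far too numerous to review one by one,
so they are prioritized by independent clinical evidence: the phenotype
terms and disease genes annotated to both members. A pair that shares
at least one phenotype *and* at least one gene is the default keep-set;
pairs surviving that filter inherit the similarity type "Siblings",
since they were obtained from sibling classes in a classification tree.

Ranking places shared genes before shared phenotypes: gene overlap is
by far the scarcer signal (phenotype annotations are dense, shared
genes are rare), so it carries more specificity per unit count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .curies import CurieId
from .kg import GENE_PREDICATE, PHENOTYPE_PREDICATE, KnowledgeGraph
from .pairs import DiseasePair

ANNOTATION_PREDICATES = (PHENOTYPE_PREDICATE, GENE_PREDICATE)


@dataclass(frozen=True)
class AnnotatedPair:
    """A candidate pair with its shared phenotype and gene evidence."""

    pair: DiseasePair
    shared_phenotypes: frozenset[CurieId]
    shared_genes: frozenset[CurieId]
    assigned_type: Optional[str] = None

    @property
    def n_phen(self) -> int:
        return len(self.shared_phenotypes)

    @property
    def n_gene(self) -> int:
        return len(self.shared_genes)


def shared_annotations(
    graph: KnowledgeGraph, pair: DiseasePair, predicate: str
) -> frozenset[CurieId]:
    """Annotation objects common to both members of a pair under one
    predicate (``has_phenotype`` or ``associated_with_gene``)."""
    if predicate not in ANNOTATION_PREDICATES:
        raise ValueError(
            f"predicate must be one of {ANNOTATION_PREDICATES}, got {predicate!r}"
        )
    return graph.annotations(pair.a, predicate) & graph.annotations(pair.b, predicate)


def annotate_pair(graph: KnowledgeGraph, pair: DiseasePair) -> AnnotatedPair:
    return AnnotatedPair(
        pair=pair,
        shared_phenotypes=shared_annotations(graph, pair, PHENOTYPE_PREDICATE),
        shared_genes=shared_annotations(graph, pair, GENE_PREDICATE),
    )


def prioritize_pairs(
    pairs: Iterable[DiseasePair],
    graph: KnowledgeGraph,
    min_phen: int = 1,
    min_gene: int = 1,
    assigned_type: Optional[str] = "Siblings",
) -> list[AnnotatedPair]:
    """Annotate pairs and keep those with at least ``min_phen`` shared
    phenotypes and ``min_gene`` shared genes.

    Ranked by shared-gene count descending, then shared-phenotype count
    descending, then canonical pair order — a total order, so the output
    is invariant to the input ordering. Thresholds of (1, 0), (0, 1) and
    (1, 1) select the shared-phenotype set, the shared-gene set, and
    their conjunction respectively.
    """
    if min_phen < 0 or min_gene < 0:
        raise ValueError("thresholds must be non-negative")
    kept = []
    for pair in set(pairs):
        ann = annotate_pair(graph, pair)
        if ann.n_phen >= min_phen and ann.n_gene >= min_gene:
            kept.append(
                AnnotatedPair(
                    pair=ann.pair,
                    shared_phenotypes=ann.shared_phenotypes,
                    shared_genes=ann.shared_genes,
                    assigned_type=assigned_type,
                )
            )
    kept.sort(key=lambda a: (-a.n_gene, -a.n_phen, a.pair))
    return kept
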