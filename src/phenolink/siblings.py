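"""Sibling derivation from ontology classification trees.

The second identification route maps each primary-namespace disease
into an ontology classification (via its xrefs into that ontology),
collects the *siblings* of the mapped classes — classes sharing at
least one direct parent — and maps those siblings back to the primary
namespace. Diseases recovered this way are candidates for phenotypical
similarity, because diseases grouped under one classification parent
tend to present homogeneous clinical pictures.

The traversal is exactly one hop up and one hop down: direct parents
and their direct children. Descendant closure (subtype derivation) is a
different relation and is deliberately not computed here. A primary
disease mapped to several ontology classes contributes the union of all
their sibling sets. Two primary diseases that merely map to the *same*
ontology class are co-mappings, not siblings, and are never emitted by
this route.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

from .curies import CurieId, normalize_prefix
from .errors import UnknownDiseaseError
from .kg import KnowledgeGraph
from .pairs import DiseasePair, PairProvenance

logger = logging.getLogger(__name__)


def _tree_members(graph: KnowledgeGraph, source: str) -> set[CurieId]:
    source = normalize_prefix(source)
    members = {n.id for n in graph.nodes.values() if n.source == source}
    for child, parent, src in graph.tree_edges:
        if src == source:
            members.add(child)
            members.add(parent)
    return members


def parents_of(graph: KnowledgeGraph, node: CurieId, source: str) -> frozenset[CurieId]:
    """Direct parents of ``node`` in one source's classification tree.
    Empty for roots; a lookup error if the node is not in that tree."""
    source = normalize_prefix(source)
    if node not in _tree_members(graph, source):
        raise UnknownDiseaseError(
            f"{node} is not part of the {source} classification tree"
        )
    return frozenset(graph.tree_parents(source).get(node, frozenset()))


def siblings_of(graph: KnowledgeGraph, node: CurieId, source: str) -> frozenset[CurieId]:
    """Classes sharing at least one direct parent with ``node``.

    The union over all parents of their children, minus the node itself.
    Symmetric: ``b in siblings_of(a)`` iff ``a in siblings_of(b)``.
    """
    parents = parents_of(graph, node, source)
    children = graph.tree_children(normalize_prefix(source))
    sibs: set[CurieId] = set()
    for parent in parents:
        sibs |= children.get(parent, set())
    sibs.discard(node)
    return frozenset(sibs)


@dataclass(frozen=True)
class TreeMapping:
    """Bidirectional mapping between primary diseases and the ontology
    classes they cross-reference. ``backward`` is the exact transpose of
    ``forward``; both are built only from xrefs whose canonical prefix
    matches the tree source."""

    forward: Mapping[CurieId, frozenset[CurieId]]
    backward: Mapping[CurieId, frozenset[CurieId]]


def build_tree_mapping(
    graph: KnowledgeGraph, primary_source: str, tree_source: str
) -> TreeMapping:
    """Map primary diseases into a tree via their in-prefix xrefs.

    Xrefs that point at identifiers absent from the tree are ignored:
    a mapping is only usable if its target actually sits in the
    classification.
    """
    tree_source = normalize_prefix(tree_source)
    members = _tree_members(graph, tree_source)
    forward: dict[CurieId, frozenset[CurieId]] = {}
    backward: dict[CurieId, set[CurieId]] = defaultdict(set)
    for disease in graph.diseases(primary_source):
        mapped = frozenset(
            x
            for x in graph.nodes[disease].xrefs
            if x.prefix == tree_source and x in members
        )
        if mapped:
            forward[disease] = mapped
            for m in mapped:
                backward[m].add(disease)
    return TreeMapping(
        forward=forward,
        backward={k: frozenset(v) for k, v in backward.items()},
    )


@dataclass(frozen=True)
class SiblingDerivation:
    """One derivation step: the query disease, the tree it was routed
    through, the shared parent, and the primary diseases recovered by
    mapping that parent's other children back."""

    query: CurieId
    route: str
    via_parent: CurieId
    similar: frozenset[CurieId]


def derive_similar_via_tree(
    graph: KnowledgeGraph, primary_source: str, tree_source: str
) -> list[SiblingDerivation]:
    """Run the three-step derivation for every primary disease:
    map into the tree, collect siblings of every mapped class, map the
    siblings back. Only derivations with a non-empty recovered set are
    emitted, one per (query, parent)."""
    tree_source = normalize_prefix(tree_source)
    mapping = build_tree_mapping(graph, primary_source, tree_source)
    if not mapping.forward:
        logger.warning(
            "no %s disease maps into the %s tree; empty result",
            primary_source,
            tree_source,
        )
        return []
    children = graph.tree_children(tree_source)
    parents = graph.tree_parents(tree_source)

    derivations: list[SiblingDerivation] = []
    for query in sorted(mapping.forward, key=str):
        per_parent: dict[CurieId, set[CurieId]] = defaultdict(set)
        for mapped in mapping.forward[query]:
            for parent in parents.get(mapped, frozenset()):
                for sib in children.get(parent, set()) - {mapped}:
                    per_parent[parent] |= mapping.backward.get(sib, frozenset())
        for parent in sorted(per_parent, key=str):
            similar = frozenset(per_parent[parent] - {query})
            if similar:
                derivations.append(
                    SiblingDerivation(
                        query=query,
                        route=tree_source,
                        via_parent=parent,
                        similar=similar,
                    )
                )
    return derivations


def pairs_from_derivations(
    derivations: Iterable[SiblingDerivation],
) -> dict[DiseasePair, PairProvenance]:
    """Collapse derivations into canonical pairs with provenance. A pair
    derivable through several trees or parents appears once."""
    out: dict[DiseasePair, PairProvenance] = {}
    for d in derivations:
        for other in d.similar:
            pair = DiseasePair(d.query, other)
            prov = out.setdefault(pair, PairProvenance())
            prov.routes.add(d.route)
            prov.via_parents.add(d.via_parent)
    return out


PairsLike = Union[
    Mapping[DiseasePair, PairProvenance],
    Iterable[Union[DiseasePair, tuple]],
]


def combine_pair_sets(*sets: PairsLike) -> dict[DiseasePair, PairProvenance]:
    """Union pair collections, merging provenance. Idempotent and
    commutative; bare (a, b) tuples are canonicalized with a logged
    note."""
    out: dict[DiseasePair, PairProvenance] = {}
    for collection in sets:
        if isinstance(collection, Mapping):
            items = collection.items()
        else:
            items = ((p, PairProvenance()) for p in collection)
        for pair, prov in items:
            if not isinstance(pair, DiseasePair):
                a, b = pair
                if str(a) > str(b):
                    logger.info("canonicalizing non-canonical pair (%s, %s)", a, b)
                pair = DiseasePair(a, b)
            merged = out.setdefault(pair, PairProvenance())
            merged.merge(prov)
    return out
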