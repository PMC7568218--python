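"""Flat-file multi-source disease knowledge graph.

The graph holds disease concepts from several resources in one node
table. Each disease node carries a set of cross-reference CURIEs
(``xrefs``) pointing at equivalent concepts in other resources — the
raw material for fingerprint similarity. Edges come in three kinds:

* ``subClassOf`` — classification-tree edges (child -> parent) within a
  single ontology source, used for sibling derivation;
* ``has_phenotype`` — disease -> phenotype-term annotations;
* ``associated_with_gene`` — disease -> gene associations.

Phenotype and gene objects are annotation endpoints only; they need not
resolve to nodes. Disease endpoints must resolve, and each source's
classification edges must be acyclic — both are hard load errors.

File dialects
-------------
``nodes.tsv`` (UTF-8, header): ``id``, ``name``, ``source``, ``xrefs``
(pipe-separated CURIEs, empty allowed).

``edges.tsv`` (header): ``subject``, ``predicate``, ``object``,
``source`` with ``predicate`` one of the three kinds above; for
``subClassOf`` the subject is the child.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .curies import CurieId, normalize_curie, normalize_prefix
from .errors import GraphLoadError, UnknownDiseaseError

TREE_PREDICATE = "subClassOf"
PHENOTYPE_PREDICATE = "has_phenotype"
GENE_PREDICATE = "associated_with_gene"
PREDICATES = (TREE_PREDICATE, PHENOTYPE_PREDICATE, GENE_PREDICATE)

NODE_COLUMNS = ["id", "name", "source", "xrefs"]
EDGE_COLUMNS = ["subject", "predicate", "object", "source"]


@dataclass(frozen=True)
class DiseaseNode:
    """A disease concept: its id, display name, owning source namespace
    and the set of cross-references curated for it."""

    id: CurieId
    name: str
    source: str
    xrefs: frozenset[CurieId] = frozenset()

    def __post_init__(self) -> None:
        source = normalize_prefix(self.source)
        object.__setattr__(self, "source", source)
        if self.id.prefix != source:
            raise GraphLoadError(
                f"node {self.id}: id prefix {self.id.prefix!r} does not match "
                f"source {source!r}"
            )
        # a node never cross-references itself
        object.__setattr__(self, "xrefs", frozenset(self.xrefs) - {self.id})


@dataclass
class KnowledgeGraph:
    """In-memory knowledge graph over normalized CURIEs."""

    nodes: dict[CurieId, DiseaseNode] = field(default_factory=dict)
    tree_edges: set[tuple[CurieId, CurieId, str]] = field(default_factory=set)
    phenotype_edges: set[tuple[CurieId, CurieId]] = field(default_factory=set)
    gene_edges: set[tuple[CurieId, CurieId]] = field(default_factory=set)

    # -- accessors -----------------------------------------------------

    def node(self, disease: CurieId) -> DiseaseNode:
        try:
            return self.nodes[disease]
        except KeyError:
            raise UnknownDiseaseError(f"unknown disease id: {disease}") from None

    def diseases(self, source: str) -> list[CurieId]:
        """Ids of all nodes owned by ``source``, sorted lexicographically."""
        source = normalize_prefix(source)
        return sorted(
            (n.id for n in self.nodes.values() if n.source == source), key=str
        )

    def annotations(self, disease: CurieId, predicate: str) -> frozenset[CurieId]:
        """Objects annotated to ``disease`` under one annotation predicate."""
        self.node(disease)  # raise for unknown ids
        if predicate == PHENOTYPE_PREDICATE:
            edges = self.phenotype_edges
        elif predicate == GENE_PREDICATE:
            edges = self.gene_edges
        else:
            raise ValueError(f"not an annotation predicate: {predicate!r}")
        return frozenset(obj for subj, obj in edges if subj == disease)

    def tree_children(self, source: str) -> dict[CurieId, set[CurieId]]:
        """parent -> set of children within one source's classification."""
        source = normalize_prefix(source)
        out: dict[CurieId, set[CurieId]] = defaultdict(set)
        for child, parent, src in self.tree_edges:
            if src == source:
                out[parent].add(child)
        return dict(out)

    def tree_parents(self, source: str) -> dict[CurieId, set[CurieId]]:
        """child -> set of parents within one source's classification."""
        source = normalize_prefix(source)
        out: dict[CurieId, set[CurieId]] = defaultdict(set)
        for child, parent, src in self.tree_edges:
            if src == source:
                out[child].add(parent)
        return dict(out)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise GraphLoadError on any
        violation (unresolvable disease endpoint, cyclic tree)."""
        missing: set[CurieId] = set()
        for child, parent, _src in self.tree_edges:
            for endpoint in (child, parent):
                if endpoint not in self.nodes:
                    missing.add(endpoint)
        for subj, _obj in self.phenotype_edges | self.gene_edges:
            if subj not in self.nodes:
                missing.add(subj)
        if missing:
            listing = ", ".join(sorted(map(str, missing)))
            raise GraphLoadError(f"edge endpoints missing from node table: {listing}")

        by_source: dict[str, nx.DiGraph] = defaultdict(nx.DiGraph)
        for child, parent, src in self.tree_edges:
            by_source[src].add_edge(child, parent)
        for src, digraph in sorted(by_source.items()):
            if not nx.is_directed_acyclic_graph(digraph):
                cycle = nx.find_cycle(digraph)
                rendered = " -> ".join(str(u) for u, _v in cycle)
                raise GraphLoadError(
                    f"classification tree for source {src!r} contains a cycle: {rendered}"
                )


# ---------------------------------------------------------------------------
# input / output


def _parse_xrefs(cell: str) -> frozenset[CurieId]:
    if not cell:
        return frozenset()
    return frozenset(normalize_curie(part) for part in cell.split("|") if part.strip())


def load_graph(nodes_path: str | Path, edges_path: str | Path) -> KnowledgeGraph:
    """Load a knowledge graph from node and edge TSVs.

    All CURIEs are normalized on the way in, so dialect duplicates such
    as ``ORPHANET:945|ORPHA:945`` collapse to a single xref. The loaded
    graph is validated before it is returned.
    """
    nodes_df = pd.read_csv(nodes_path, sep="\t", dtype=str, keep_default_na=False)
    edges_df = pd.read_csv(edges_path, sep="\t", dtype=str, keep_default_na=False)
    for df, cols, path in (
        (nodes_df, NODE_COLUMNS, nodes_path),
        (edges_df, EDGE_COLUMNS, edges_path),
    ):
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise GraphLoadError(f"{path}: missing columns {missing_cols}")

    graph = KnowledgeGraph()
    for row in nodes_df.itertuples(index=False):
        node = DiseaseNode(
            id=normalize_curie(row.id),
            name=row.name,
            source=row.source,
            xrefs=_parse_xrefs(row.xrefs),
        )
        if node.id in graph.nodes:
            raise GraphLoadError(f"duplicate node id: {node.id}")
        graph.nodes[node.id] = node

    for row in edges_df.itertuples(index=False):
        subject = normalize_curie(row.subject)
        obj = normalize_curie(row.object)
        if row.predicate == TREE_PREDICATE:
            graph.tree_edges.add((subject, obj, normalize_prefix(row.source)))
        elif row.predicate == PHENOTYPE_PREDICATE:
            graph.phenotype_edges.add((subject, obj))
        elif row.predicate == GENE_PREDICATE:
            graph.gene_edges.add((subject, obj))
        else:
            raise GraphLoadError(
                f"unknown predicate {row.predicate!r}; expected one of {PREDICATES}"
            )

    graph.validate()
    return graph


def write_graph(
    graph: KnowledgeGraph, nodes_path: str | Path, edges_path: str | Path
) -> None:
    """Write a graph back to the TSV dialects read by :func:`load_graph`.

    Rows and xref lists are emitted in sorted order, so writing the same
    graph twice produces byte-identical files.
    """
    node_rows = [
        {
            "id": str(node.id),
            "name": node.name,
            "source": node.source,
            "xrefs": "|".join(sorted(map(str, node.xrefs))),
        }
        for node in sorted(graph.nodes.values(), key=lambda n: str(n.id))
    ]
    edge_rows = sorted(
        [
            {"subject": str(c), "predicate": TREE_PREDICATE, "object": str(p), "source": s}
            for c, p, s in graph.tree_edges
        ]
        + [
            {"subject": str(s), "predicate": PHENOTYPE_PREDICATE, "object": str(o), "source": ""}
            for s, o in graph.phenotype_edges
        ]
        + [
            {"subject": str(s), "predicate": GENE_PREDICATE, "object": str(o), "source": ""}
            for s, o in graph.gene_edges
        ],
        key=lambda r: (r["predicate"], r["subject"], r["object"], r["source"]),
    )
    pd.DataFrame(node_rows, columns=NODE_COLUMNS).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(edge_rows, columns=EDGE_COLUMNS).to_csv(edges_path, sep="\t", index=False)


def read_obo(path: str | Path, source: str | None = None) -> KnowledgeGraph:
    """Read an OBO-format ontology into a knowledge graph.

    ``is_a`` relations become classification-tree edges and ``xref``
    lines become node xrefs. ``source`` defaults to the prefix of the
    first term id; terms from other namespaces are skipped.
    Requires the optional ``obonet`` dependency.
    """
    import obonet  # local import: optional dependency

    onto = obonet.read_obo(str(path))
    graph = KnowledgeGraph()
    ids: dict[str, CurieId] = {}
    for raw_id, data in onto.nodes(data=True):
        try:
            curie = normalize_curie(raw_id)
        except Exception:
            continue
        if source is None:
            source = curie.prefix
        if curie.prefix != normalize_prefix(source):
            continue
        xrefs = frozenset(
            normalize_curie(x) for x in data.get("xref", []) if ":" in x
        )
        ids[raw_id] = curie
        graph.nodes[curie] = DiseaseNode(
            id=curie, name=data.get("name", ""), source=curie.prefix, xrefs=xrefs
        )
    src = normalize_prefix(source) if source else ""
    for child_raw, parent_raw, key in onto.edges(keys=True):
        if key != "is_a":
            continue
        if child_raw in ids and parent_raw in ids:
            graph.tree_edges.add((ids[child_raw], ids[parent_raw], src))
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# xref queries


def xrefs_by_prefix(
    graph: KnowledgeGraph, disease: CurieId, prefix: str
) -> frozenset[CurieId]:
    """A disease's cross-references into one namespace.

    Matching is by canonical prefix equality after normalization, so
    ``ORPHA`` retrieves xrefs recorded under either Orphanet dialect.
    """
    wanted = normalize_prefix(prefix)
    return frozenset(x for x in graph.node(disease).xrefs if x.prefix == wanted)


def diseases_with_any_xref(
    graph: KnowledgeGraph, source: str, prefixes: Iterable[str]
) -> list[CurieId]:
    """Ids of diseases from ``source`` with at least one xref into any of
    the listed namespaces, sorted lexicographically. The complement (the
    excluded, unmappable diseases) is ``diseases(source)`` minus this."""
    wanted = {normalize_prefix(p) for p in prefixes}
    if not wanted:
        raise ValueError("prefixes must be non-empty")
    out = [
        d
        for d in graph.diseases(source)
        if any(x.prefix in wanted for x in graph.nodes[d].xrefs)
    ]
    return sorted(out, key=str)
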