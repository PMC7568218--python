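"""Seeded synthetic disease knowledge graphs with planted ground truth.

Real rare-disease knowledge graphs live in a graph database and cannot
be redistributed, so every pipeline stage here is exercised against
synthetic graphs that emulate the statistical structure of the real
data:

* a primary disease namespace (``GARD``-like) whose nodes carry
  cross-references into three mapping namespaces (Orphanet-, OMIM- and
  UMLS-like), with per-source coverage below 1 and a fraction of
  diseases carrying no mapping at all (the unmappable diseases the
  fingerprint route must exclude);
* planted **duplicate** pairs — two records for the same clinical
  entity, hence identical xref sets and cosine exactly 1;
* planted **subtype** pairs — partially shared xref sets (all but one
  mapping shared), giving a high but sub-unit cosine;
* planted **sibling families** — groups of diseases that share no
  mappings but sit under a common parent in each ontology
  classification tree and share family-level phenotype and gene
  annotations, so only the tree route can recover them;
* background diseases with private mappings and random annotations,
  plus optional planted *collision* pairs: clinically unrelated
  diseases that nevertheless share a mapping (the false-positive mode
  of the fingerprint route).

Everything is driven by one integer seed through per-component
sub-streams (spawned from a single ``SeedSequence``), so adding draws
to one component never reshuffles another, and identical configs give
byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .curies import CurieId
from .evaluate import LABELS, write_labels
from .kg import DiseaseNode, KnowledgeGraph, write_graph
from .pairs import DiseasePair

PRIMARY_SOURCE = "GARD"
XREF_PREFIXES = ("ORPHA", "OMIM", "UMLS")
TREE_SOURCES = ("MONDO", "ORPHA")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Coverage and exclusion defaults follow the observed shape of the
    real mapping data: roughly half the diseases carry a mapping to any
    given resource, and about a fifth carry none at all. Family-level
    annotation sharing defaults to certainty so that, without noise,
    the phenotype-and-gene filter keeps exactly the planted sibling
    pairs.
    """

    seed: int = 0
    n_diseases: int = 60
    xref_prefixes: tuple[str, ...] = XREF_PREFIXES
    #: per-source probability that a disease carries an xref there
    coverage: Mapping[str, float] = field(
        default_factory=lambda: {"ORPHA": 0.45, "OMIM": 0.52, "UMLS": 0.53}
    )
    #: probability a background disease carries no xref at all
    p_no_mapping: float = 0.22
    n_duplicate_pairs: int = 5
    n_subtype_pairs: int = 5
    n_sibling_families: int = 4
    family_size: int = 4
    tree_sources: tuple[str, ...] = TREE_SOURCES
    phenotype_pool: int = 150
    gene_pool: int = 80
    #: inclusive (lo, hi) range for per-disease annotation counts
    n_phen_per_disease: tuple[int, int] = (2, 8)
    n_gene_per_disease: tuple[int, int] = (0, 2)
    #: probability a planted sibling pair shares >= 1 annotation
    sibling_share_phen: float = 1.0
    sibling_share_gene: float = 1.0
    #: planted unrelated-but-sharing-one-mapping pairs (default off)
    n_collision_pairs: int = 0
    #: probability a ground-truth label is corrupted in the label table
    label_noise: float = 0.0

    def validate(self) -> None:
        from .errors import ConfigError

        probs = [self.p_no_mapping, self.sibling_share_phen, self.sibling_share_gene,
                 self.label_noise, *self.coverage.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        counts = [self.n_diseases, self.n_duplicate_pairs, self.n_subtype_pairs,
                  self.n_sibling_families, self.family_size, self.phenotype_pool,
                  self.gene_pool, self.n_collision_pairs]
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be non-negative")
        planted = (
            2 * self.n_duplicate_pairs
            + 2 * self.n_subtype_pairs
            + self.n_sibling_families * self.family_size
        )
        background = self.n_diseases - planted
        if background < 0:
            raise ConfigError(
                f"planted structure needs {planted} diseases, "
                f"config allows only {self.n_diseases}"
            )
        if self.n_collision_pairs * 2 > background:
            raise ConfigError(
                f"{self.n_collision_pairs} collision pairs need "
                f"{2 * self.n_collision_pairs} background diseases, have {background}"
            )
        if self.n_sibling_families and self.family_size < 2:
            raise ConfigError("sibling families need family_size >= 2")
        for name in ("n_phen_per_disease", "n_gene_per_disease"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} must be a non-negative (lo, hi) range")
        missing = [p for p in self.xref_prefixes if p not in self.coverage]
        if missing:
            raise ConfigError(f"coverage missing for prefixes: {missing}")


@dataclass
class GroundTruth:
    """What the generator planted, for pipeline-recovery checks."""

    pair_types: dict[DiseasePair, str] = field(default_factory=dict)
    xrefs: dict[CurieId, frozenset[CurieId]] = field(default_factory=dict)
    families: list[tuple[CurieId, ...]] = field(default_factory=list)
    expected_universe_size: int = 0
    excluded_no_mapping: list[CurieId] = field(default_factory=list)

    def pairs_of_type(self, label: str) -> set[DiseasePair]:
        return {p for p, t in self.pair_types.items() if t == label}


class _XrefMint:
    """Deterministic source of fresh identifiers. Distinct mints use
    distinct numeric bases so ids never collide across components."""

    def __init__(self, base: int = 700000) -> None:
        self._base = base
        self._next: dict[str, int] = {}

    def fresh(self, prefix: str) -> CurieId:
        n = self._next.get(prefix, 0)
        self._next[prefix] = n + 1
        if prefix == "UMLS":
            return CurieId(prefix, f"C{self._base + n}")
        return CurieId(prefix, str(self._base + n))


def _gard_id(i: int) -> CurieId:
    return CurieId(PRIMARY_SOURCE, f"{i + 1:07d}")


def simulate_knowledge_graph(
    config: SimulationConfig,
) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a graph and its ground truth. Fully deterministic in
    ``config.seed``."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_xref = np.random.default_rng(streams[0])
    rng_annot = np.random.default_rng(streams[1])
    rng_label = np.random.default_rng(streams[2])
    rng_misc = np.random.default_rng(streams[3])

    mint = _XrefMint()
    truth = GroundTruth()
    graph = KnowledgeGraph()

    diseases = [_gard_id(i) for i in range(config.n_diseases)]
    cursor = 0

    def take(k: int) -> list[CurieId]:
        nonlocal cursor
        chunk = diseases[cursor : cursor + k]
        cursor += k
        return chunk

    prefixes = list(config.xref_prefixes)

    def draw_xrefs(minimum: int = 0) -> set[CurieId]:
        """One fresh xref per covered source, forcing at least
        ``minimum`` sources when the coverage draw falls short."""
        covered = [p for p in prefixes if rng_xref.random() < config.coverage[p]]
        while len(covered) < minimum:
            extra = [p for p in prefixes if p not in covered]
            covered.append(extra[rng_xref.integers(len(extra))])
        return {mint.fresh(p) for p in covered}

    xrefs: dict[CurieId, set[CurieId]] = {}

    # -- duplicates: identical non-empty xref sets ---------------------
    for _ in range(config.n_duplicate_pairs):
        a, b = take(2)
        shared = draw_xrefs(minimum=1)
        xrefs[a] = set(shared)
        xrefs[b] = set(shared)
        truth.pair_types[DiseasePair(a, b)] = "Duplicated"

    # -- subtypes: all-but-one xref shared -----------------------------
    for _ in range(config.n_subtype_pairs):
        a, b = take(2)
        base = draw_xrefs(minimum=2)
        xrefs[a] = set(base)
        dropped = sorted(base, key=str)[rng_xref.integers(len(base))]
        xrefs[b] = (base - {dropped}) | {mint.fresh(dropped.prefix)}
        truth.pair_types[DiseasePair(a, b)] = "Subtypes"

    # -- sibling families: tree structure, no shared mappings ----------
    tree_mint = _XrefMint(base=800000)
    for fam in range(config.n_sibling_families):
        members = tuple(take(config.family_size))
        truth.families.append(members)
        for i, a in enumerate(members):
            xrefs[a] = draw_xrefs()
            for b in members[i + 1 :]:
                truth.pair_types[DiseasePair(a, b)] = "Siblings"
        for tree in config.tree_sources:
            parent = tree_mint.fresh(tree)
            graph.nodes[parent] = DiseaseNode(
                id=parent, name=f"synthetic {tree} family {fam} parent", source=tree
            )
            for member in members:
                child = tree_mint.fresh(tree)
                graph.nodes[child] = DiseaseNode(
                    id=child, name=f"synthetic {tree} class for {member}", source=tree
                )
                graph.tree_edges.add((child, parent, tree))
                xrefs[member].add(child)

    # -- background diseases -------------------------------------------
    background = diseases[cursor:]
    for d in background:
        if rng_xref.random() < config.p_no_mapping:
            xrefs[d] = set()
        else:
            xrefs[d] = draw_xrefs()

    # -- collisions: unrelated pairs sharing one mapping ---------------
    if config.n_collision_pairs:
        chosen = [
            background[i]
            for i in rng_misc.choice(
                len(background), size=2 * config.n_collision_pairs, replace=False
            )
        ]
        for a, b in zip(chosen[::2], chosen[1::2]):
            shared = mint.fresh(prefixes[int(rng_misc.integers(len(prefixes)))])
            xrefs[a].add(shared)
            xrefs[b].add(shared)
            truth.pair_types[DiseasePair(a, b)] = "Unrelated"

    # -- primary nodes -------------------------------------------------
    for d in diseases:
        graph.nodes[d] = DiseaseNode(
            id=d,
            name=f"synthetic disease {d.local_id}",
            source=PRIMARY_SOURCE,
            xrefs=frozenset(xrefs[d]),
        )
        truth.xrefs[d] = frozenset(xrefs[d])

    # -- annotations ---------------------------------------------------
    phen_pool = [CurieId("HP", f"{i + 1:07d}") for i in range(config.phenotype_pool)]
    gene_pool = [CurieId("OMIM", str(100000 + i)) for i in range(config.gene_pool)]

    def sample(pool: list[CurieId], lo: int, hi: int) -> set[CurieId]:
        k = int(rng_annot.integers(lo, hi + 1))
        if k == 0 or not pool:
            return set()
        idx = rng_annot.choice(len(pool), size=min(k, len(pool)), replace=False)
        return {pool[i] for i in idx}

    annot_phen: dict[CurieId, set[CurieId]] = {}
    annot_gene: dict[CurieId, set[CurieId]] = {}
    for d in diseases:
        annot_phen[d] = sample(phen_pool, *config.n_phen_per_disease)
        annot_gene[d] = sample(gene_pool, *config.n_gene_per_disease)

    # family-level shared annotations: each member carries the family
    # term with probability sqrt(p), so a pair shares it with ~p
    fam_mint = _XrefMint(base=900000)
    for members in truth.families:
        fam_phen = fam_mint.fresh("HP")
        fam_gene = fam_mint.fresh("OMIM")
        p_member_phen = config.sibling_share_phen ** 0.5
        p_member_gene = config.sibling_share_gene ** 0.5
        for member in members:
            if rng_annot.random() < p_member_phen:
                annot_phen[member].add(fam_phen)
            if rng_annot.random() < p_member_gene:
                annot_gene[member].add(fam_gene)

    for d in diseases:
        for term in annot_phen[d]:
            graph.phenotype_edges.add((d, term))
        for gene in annot_gene[d]:
            graph.gene_edges.add((d, gene))

    # -- ground-truth bookkeeping --------------------------------------
    wanted = set(config.xref_prefixes)
    universe = {
        x
        for d in diseases
        for x in xrefs[d]
        if x.prefix in wanted and any(y.prefix in wanted for y in xrefs[d])
    }
    truth.expected_universe_size = len(universe)
    truth.excluded_no_mapping = sorted(
        (d for d in diseases if not any(x.prefix in wanted for x in xrefs[d])), key=str
    )

    graph.validate()
    return graph, truth


def noisy_labels(
    truth: GroundTruth, config: SimulationConfig
) -> dict[DiseasePair, str]:
    """The curation-table labels: planted pair types, each corrupted to
    a different random label with probability ``label_noise``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    out: dict[DiseasePair, str] = {}
    for pair in sorted(truth.pair_types):
        label = truth.pair_types[pair]
        if config.label_noise and rng.random() < config.label_noise:
            others = [l for l in LABELS if l != label]
            label = others[int(rng.integers(len(others)))]
        out[pair] = label
    return out


def write_fixture(
    graph: KnowledgeGraph,
    truth: GroundTruth,
    out_dir: str | Path,
    config: Optional[SimulationConfig] = None,
) -> dict[str, Path]:
    """Write nodes/edges TSVs, the (possibly noised) label TSV and a
    JSON manifest recording the config. Reloadable by ``load_graph``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
        "labels": out / "labels.tsv",
        "manifest": out / "manifest.json",
    }
    write_graph(graph, paths["nodes"], paths["edges"])
    labels = (
        noisy_labels(truth, config)
        if config is not None
        else dict(sorted(truth.pair_types.items()))
    )
    write_labels(labels, paths["labels"])
    manifest = {
        "config": _config_dict(config) if config is not None else None,
        "n_nodes": len(graph.nodes),
        "n_tree_edges": len(graph.tree_edges),
        "n_phenotype_edges": len(graph.phenotype_edges),
        "n_gene_edges": len(graph.gene_edges),
        "expected_universe_size": truth.expected_universe_size,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["coverage"] = dict(d["coverage"])
    return d
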