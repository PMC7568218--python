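"""Binary mapping fingerprints and cosine similarity.

Each primary-namespace disease is represented as a binary vector over
the *mapping universe* — the enumerated set of distinct cross-reference
CURIEs (restricted to the chosen namespaces) carried by any eligible
disease. A bit is 1 when the disease carries that mapping. Similarity
between two diseases is the cosine of the angle between their
fingerprints, which for binary vectors reduces to

    cos(a, b) = |A ∩ B| / sqrt(|A| · |B|)

where A and B are the sets of set bits. Scores are kept at full floating
precision; two-decimal rounding is a display concern only, so that
binning at 0.5 and 0.7 boundaries never depends on rounding.

Diseases with no in-universe mapping are excluded up front (an all-zero
vector has no direction, so its cosine is undefined), and pairs sharing
no mapping (score exactly 0) are dropped from the candidate list.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .curies import CurieId, normalize_prefix
from .errors import (
    BinSpecError,
    DimensionError,
    InsufficientInputError,
    UndefinedSimilarityError,
    UniverseError,
)
from .kg import KnowledgeGraph, diseases_with_any_xref
from .pairs import DiseasePair


@dataclass(frozen=True)
class MappingUniverse:
    """The ordered set of distinct mappings defining fingerprint
    dimension. Order is lexicographic by rendered CURIE, so the universe
    (and every bit position) is deterministic for a given graph."""

    entries: tuple[CurieId, ...]

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise UniverseError("universe entries must be distinct")
        object.__setattr__(
            self, "_index", {curie: i for i, curie in enumerate(self.entries)}
        )

    @property
    def index(self) -> dict[CurieId, int]:
        return self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary vector: the set of universe positions equal to 1."""

    disease: CurieId
    bits: frozenset[int]
    dim: int

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.dim:
            raise DimensionError(
                f"fingerprint for {self.disease} has bit beyond dimension {self.dim}"
            )


@dataclass(frozen=True)
class SimilarityRecord:
    """One scored candidate pair with its shared-mapping evidence."""

    pair: DiseasePair
    score: float
    n_shared: int
    shared: frozenset[CurieId] = frozenset()


def build_universe(
    graph: KnowledgeGraph, source: str, prefixes: Iterable[str]
) -> MappingUniverse:
    """Enumerate the distinct in-prefix mappings over all eligible
    diseases of ``source``. A mapping shared by many diseases is still a
    single dimension."""
    wanted = {normalize_prefix(p) for p in prefixes}
    eligible = diseases_with_any_xref(graph, source, wanted)
    entries = sorted(
        {
            x
            for d in eligible
            for x in graph.nodes[d].xrefs
            if x.prefix in wanted
        },
        key=str,
    )
    if not entries:
        raise UniverseError(
            f"no disease of source {source!r} has an xref in prefixes {sorted(wanted)}"
        )
    return MappingUniverse(tuple(entries))


def build_fingerprint(
    universe: MappingUniverse, disease: CurieId, xrefs: Iterable[CurieId]
) -> Fingerprint:
    """Project a disease's xref set onto the universe."""
    bits = frozenset(universe.index[x] for x in xrefs if x in universe.index)
    return Fingerprint(disease=disease, bits=bits, dim=len(universe))


def build_fingerprints(
    graph: KnowledgeGraph,
    universe: MappingUniverse,
    source: str,
    prefixes: Iterable[str],
) -> dict[CurieId, Fingerprint]:
    """Fingerprints for every eligible disease of ``source``."""
    wanted = {normalize_prefix(p) for p in prefixes}
    out = {}
    for d in diseases_with_any_xref(graph, source, wanted):
        out[d] = build_fingerprint(universe, d, graph.nodes[d].xrefs)
    return out


def cosine_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Binary cosine similarity of two fingerprints over one universe.

    Symmetric, in [0, 1]; exactly 1 iff the bit sets are identical and
    non-empty, exactly 0 iff they are disjoint.
    """
    if a.dim != b.dim:
        raise DimensionError(
            f"fingerprints have different dimensions ({a.dim} vs {b.dim})"
        )
    if not a.bits or not b.bits:
        raise UndefinedSimilarityError(
            "cosine similarity is undefined for an all-zero fingerprint"
        )
    shared = len(a.bits & b.bits)
    if shared == 0:
        return 0.0
    if a.bits == b.bits:
        return 1.0
    return shared / math.sqrt(len(a.bits) * len(b.bits))


def candidate_pair_count(n_diseases: int) -> int:
    """Number of unordered candidate pairs among ``n_diseases`` eligible
    diseases: n(n-1)/2, evaluated exactly without enumeration."""
    if n_diseases < 0:
        raise ValueError("n_diseases must be non-negative")
    return n_diseases * (n_diseases - 1) // 2


def enumerate_similar_pairs(
    graph: KnowledgeGraph, source: str, prefixes: Iterable[str]
) -> list[SimilarityRecord]:
    """Score every unordered pair of eligible diseases and keep those
    sharing at least one mapping (score > 0).

    Equivalent to brute-forcing all n(n-1)/2 pairs; implemented with an
    inverted index from mapping to carrying diseases, so only pairs that
    actually co-occur on some mapping are touched. Records are sorted by
    score descending, ties broken by canonical pair order.
    """
    prefixes = {normalize_prefix(p) for p in prefixes}
    universe = build_universe(graph, source, prefixes)
    fingerprints = build_fingerprints(graph, universe, source, prefixes)
    if len(fingerprints) < 2:
        raise InsufficientInputError(
            f"need at least 2 eligible diseases, found {len(fingerprints)}"
        )

    postings: dict[int, list[CurieId]] = defaultdict(list)
    for disease in sorted(fingerprints, key=str):
        for bit in fingerprints[disease].bits:
            postings[bit].append(disease)

    shared_counts: Counter[DiseasePair] = Counter()
    for carriers in postings.values():
        for d1, d2 in itertools.combinations(carriers, 2):
            shared_counts[DiseasePair(d1, d2)] += 1

    records = []
    for pair, n_shared in shared_counts.items():
        fa, fb = fingerprints[pair.a], fingerprints[pair.b]
        score = cosine_similarity(fa, fb)
        shared = frozenset(universe.entries[i] for i in fa.bits & fb.bits)
        records.append(
            SimilarityRecord(pair=pair, score=score, n_shared=n_shared, shared=shared)
        )
    records.sort(key=lambda r: (-r.score, r.pair))
    return records


# ---------------------------------------------------------------------------
# score bins


@dataclass(frozen=True)
class ScoreBin:
    """A half-open or closed score interval with a display label."""

    label: str
    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    def contains(self, score: float) -> bool:
        above = score > self.lo if self.lo_open else score >= self.lo
        below = score < self.hi if self.hi_open else score <= self.hi
        return above and below


#: Bin layout used when summarizing raw similarity scores: identical
#: fingerprints, high-but-imperfect overlap, and low overlap.
DEFAULT_BINS: tuple[ScoreBin, ...] = (
    ScoreBin("similarity = 1", 1.0, 1.0),
    ScoreBin("0.5 <= similarity < 1", 0.5, 1.0, hi_open=True),
    ScoreBin("0 < similarity < 0.5", 0.0, 0.5, lo_open=True, hi_open=True),
)

#: Bin layout used in the curated-review cross-tabulation, which splits
#: the predicted-similar region at 0.7.
REVIEW_BINS: tuple[ScoreBin, ...] = (
    ScoreBin("0.7 <= score <= 1", 0.7, 1.0),
    ScoreBin("0.5 <= score < 0.7", 0.5, 0.7, hi_open=True),
    ScoreBin("score < 0.5", 0.0, 0.5, lo_open=True, hi_open=True),
)


def validate_bins(bins: Sequence[ScoreBin]) -> list[ScoreBin]:
    """Check that ``bins`` partition the half-open interval (0, 1]:
    no overlap, no gap. Returns the bins sorted by lower edge."""
    if not bins:
        raise BinSpecError("empty bin specification")
    ordered = sorted(bins, key=lambda b: (b.lo, b.hi))
    for b in ordered:
        if b.lo > b.hi or (b.lo == b.hi and (b.lo_open or b.hi_open)):
            raise BinSpecError(f"empty or inverted bin: {b.label!r}")
    first, last = ordered[0], ordered[-1]
    if not (first.lo == 0.0 and first.lo_open):
        raise BinSpecError("bins must start open at 0 (scores of 0 are excluded)")
    if not (last.hi == 1.0 and not last.hi_open):
        raise BinSpecError("bins must end closed at 1")
    for left, right in zip(ordered, ordered[1:]):
        if left.hi != right.lo:
            raise BinSpecError(
                f"gap or overlap between {left.label!r} and {right.label!r}"
            )
        if left.hi_open == right.lo_open:
            kind = "overlap" if not left.hi_open else "gap"
            raise BinSpecError(
                f"{kind} at score {left.hi} between {left.label!r} and {right.label!r}"
            )
    return ordered


def bin_label(score: float, bins: Sequence[ScoreBin]) -> str:
    """The label of the unique bin containing ``score``."""
    hits = [b.label for b in bins if b.contains(score)]
    if len(hits) != 1:
        raise BinSpecError(f"score {score} falls in {len(hits)} bins")
    return hits[0]


def bin_scores(
    records: Iterable[SimilarityRecord], bins: Sequence[ScoreBin] = DEFAULT_BINS
) -> dict[str, int]:
    """Count records per score bin. The counts partition the input."""
    ordered = validate_bins(bins)
    counts = {b.label: 0 for b in ordered}
    for rec in records:
        counts[bin_label(rec.score, ordered)] += 1
    return counts
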