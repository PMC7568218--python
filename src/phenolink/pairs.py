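"""Canonical unordered disease pairs.

Both identification approaches (mapping-fingerprint similarity and
classification-tree sibling derivation) emit pairs of primary-namespace
diseases. A pair is stored in one canonical orientation — members sorted
lexicographically by rendered CURIE — so that results from different
routes can be unioned and intersected without orientation bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .curies import CurieId


@dataclass(frozen=True, order=True)
class DiseasePair:
    """An unordered pair of disease ids, canonically ordered."""

    a: CurieId
    b: CurieId

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-pair is not a valid disease pair: {self.a}")
        if str(self.a) > str(self.b):
            first, second = self.b, self.a
            object.__setattr__(self, "a", first)
            object.__setattr__(self, "b", second)

    def __iter__(self):
        return iter((self.a, self.b))

    def __str__(self) -> str:
        return f"({self.a}, {self.b})"


@dataclass
class PairProvenance:
    """Which derivation routes produced a pair, and through which tree
    parents (empty for routes that do not traverse a tree)."""

    routes: set = field(default_factory=set)
    via_parents: set = field(default_factory=set)

    def merge(self, other: "PairProvenance") -> None:
        self.routes |= other.routes
        self.via_parents |= other.via_parents
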