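"""Compact identifiers (CURIEs) and their normalization.

Every concept in the knowledge graph — diseases, ontology classes,
phenotype terms, genes — is addressed by a CURIE of the form
``PREFIX:localid``. Source resources are inconsistent about prefix
spelling (Orphanet concepts appear both as ``ORPHA:945`` and
``ORPHANET:945``), so all identifiers are funnelled through
:func:`normalize_curie` on ingest and a single canonical spelling is
used everywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import CurieParseError

#: Dialect prefixes collapsed to one canonical form on normalization.
#: The canonical Orphanet prefix is the short form; the long form is
#: accepted on input and never emitted.
PREFIX_ALIASES: dict[str, str] = {
    "ORPHANET": "ORPHA",
    "HPO": "HP",
}

_PREFIX_RE = re.compile(r"^[A-Z]+$")


@dataclass(frozen=True, order=True)
class CurieId:
    """A normalized namespaced identifier: an uppercase prefix plus an
    opaque local id. Local ids carry no semantics here (no checksum or
    range validation); they are compared as strings."""

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not _PREFIX_RE.match(self.prefix):
            raise CurieParseError(
                f"invalid CURIE prefix {self.prefix!r}: must be one or more A-Z characters"
            )
        if not self.local_id or any(c.isspace() for c in self.local_id):
            raise CurieParseError(
                f"invalid CURIE local id {self.local_id!r}: must be non-empty, no whitespace"
            )

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __repr__(self) -> str:
        return f"CurieId({str(self)!r})"


def normalize_prefix(token: str) -> str:
    """Uppercase a namespace token and collapse dialect spellings."""
    up = token.strip().upper()
    return PREFIX_ALIASES.get(up, up)


def normalize_curie(raw: str) -> CurieId:
    """Parse ``raw`` into a canonical :class:`CurieId`.

    The prefix is uppercased, dialect prefixes are collapsed
    (``ORPHANET`` becomes ``ORPHA``), and surrounding whitespace is
    stripped. Raises :class:`CurieParseError` for anything that is not
    exactly ``prefix:localid``.
    """
    if not isinstance(raw, str):
        raise CurieParseError(f"cannot parse CURIE from non-string {raw!r}")
    text = raw.strip()
    if text.count(":") != 1:
        raise CurieParseError(
            f"cannot parse CURIE {raw!r}: expected exactly one ':' separator"
        )
    prefix, local = text.split(":")
    prefix = normalize_prefix(prefix)
    local = local.strip()
    if not prefix or not local:
        raise CurieParseError(f"cannot parse CURIE {raw!r}: empty prefix or local id")
    try:
        return CurieId(prefix, local)
    except CurieParseError as exc:
        raise CurieParseError(f"cannot parse CURIE {raw!r}: {exc}") from None
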