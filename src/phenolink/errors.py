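"""Exception hierarchy shared across the package."""


class PhenolinkError(Exception):
    """Base class for all phenolink errors."""


class CurieParseError(PhenolinkError, ValueError):
    """A string could not be parsed as a PREFIX:localid identifier."""


class GraphLoadError(PhenolinkError):
    """A knowledge-graph file violated the expected schema or invariants."""


class UnknownDiseaseError(PhenolinkError, KeyError):
    """A disease identifier does not resolve to a node in the graph."""


class UniverseError(PhenolinkError):
    """The mapping universe could not be built (no in-prefix xrefs)."""


class DimensionError(PhenolinkError):
    """Two fingerprints belong to universes of different dimension."""


class UndefinedSimilarityError(PhenolinkError):
    """Cosine similarity is undefined for an all-zero fingerprint."""


class InsufficientInputError(PhenolinkError):
    """Fewer eligible diseases than the operation requires."""


class BinSpecError(PhenolinkError):
    """A score-bin specification overlaps or leaves gaps over (0, 1]."""


class MetricsUndefinedError(PhenolinkError):
    """Precision/recall cannot be computed (e.g. every record excluded)."""


class ConfigError(PhenolinkError):
    """A simulation or run configuration is infeasible or inconsistent."""
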