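"""Evaluation against curated similarity labels.

Expert curation assigns each scored disease pair one of five labels:
``Duplicated``, ``Siblings`` and ``Subtypes`` count as phenotypically
similar; ``Unrelated`` does not; ``Ungrouped`` marks pairs the
reviewers could not decide, which are excluded from every metric
denominator. Classification is by similarity-score threshold — a pair
is *predicted* similar when its score is at or above the threshold
(0.5 by default, with the boundary inclusive).

From the resulting confusion matrix:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 · precision · recall / (precision + recall)

Metrics are carried at full precision; whole-percent rounding is a
display concern. A metric whose denominator is zero is reported as
undefined (``None``), never as 0.

The module also cross-tabulates labels against score bins and accounts
for the union of the two identification approaches via
inclusion-exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import GraphLoadError, MetricsUndefinedError
from .fingerprints import REVIEW_BINS, ScoreBin, SimilarityRecord, bin_label, validate_bins
from .pairs import DiseasePair

LABELS = ("Duplicated", "Siblings", "Subtypes", "Unrelated", "Ungrouped")
SIMILAR_LABELS = frozenset({"Duplicated", "Siblings", "Subtypes"})
UNGROUPED = "Ungrouped"

#: A scored, labeled record: either a full SimilarityRecord or a bare
#: score, paired with a review label.
Labeled = Tuple[Union[SimilarityRecord, float], str]


def _score_of(item: Union[SimilarityRecord, float]) -> float:
    return item.score if isinstance(item, SimilarityRecord) else float(item)


def _check_label(label: str) -> str:
    if label not in LABELS:
        raise ValueError(f"unknown review label {label!r}; expected one of {LABELS}")
    return label


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix counts and the derived retrieval metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float
    n_excluded_ungrouped: int = 0

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def f_measure(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "threshold": self.threshold,
            "n_excluded_ungrouped": self.n_excluded_ungrouped,
        }


def percent(numerator: float, denominator: float) -> int:
    """A ratio rendered as a whole percent, as used in summary reporting."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    return round(100 * numerator / denominator)


def compute_metrics(labeled: Iterable[Labeled], threshold: float = 0.5) -> Metrics:
    """Score-threshold classification against curated labels.

    Predicted-similar means score >= threshold. Ungrouped records are
    removed before counting; if nothing remains the metrics are
    undefined and an error is raised.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    tp = fp = fn = tn = excluded = 0
    total = 0
    for item, label in labeled:
        total += 1
        _check_label(label)
        if label == UNGROUPED:
            excluded += 1
            continue
        predicted = _score_of(item) >= threshold
        similar = label in SIMILAR_LABELS
        if similar and predicted:
            tp += 1
        elif not similar and predicted:
            fp += 1
        elif similar and not predicted:
            fn += 1
        else:
            tn += 1
    if total == 0 or excluded == total:
        raise MetricsUndefinedError(
            "no usable records: every record is Ungrouped (or input is empty)"
        )
    return Metrics(
        tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold, n_excluded_ungrouped=excluded
    )


# ---------------------------------------------------------------------------
# label x score-bin cross-tabulation


@dataclass
class EvaluationTable:
    """Counts of curated labels cross-tabulated by score bin."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    bins: Sequence[ScoreBin] = REVIEW_BINS

    def label_marginals(self) -> dict[str, int]:
        out = {label: 0 for label in LABELS}
        for (label, _bin), n in self.counts.items():
            out[label] += n
        return out

    def bin_marginals(self) -> dict[str, int]:
        out = {b.label: 0 for b in self.bins}
        for (_label, bin_lab), n in self.counts.items():
            out[bin_lab] += n
        return out

    def n_similar(self) -> int:
        return sum(n for l, n in self.label_marginals().items() if l in SIMILAR_LABELS)

    def total(self) -> int:
        return sum(self.counts.values())


def crosstab(
    labeled: Iterable[Labeled], bins: Sequence[ScoreBin] = REVIEW_BINS
) -> EvaluationTable:
    """Tally labeled records into (label, score-bin) cells. Marginal
    sums over labels and over bins both reproduce the record total."""
    ordered = validate_bins(bins)
    table = EvaluationTable(bins=tuple(ordered))
    for item, label in labeled:
        _check_label(label)
        key = (label, bin_label(_score_of(item), ordered))
        table.counts[key] = table.counts.get(key, 0) + 1
    return table


def records_from_counts(
    counts: Mapping[tuple[str, str], int], bins: Sequence[ScoreBin] = REVIEW_BINS
) -> list[Labeled]:
    """Expand a published (label, bin) count table into labeled records,
    each carrying a representative score inside its bin (the interval
    midpoint, or the point itself for a degenerate bin). Lets printed
    evaluation tables be replayed through :func:`compute_metrics`."""
    ordered = validate_bins(bins)
    by_label = {b.label: b for b in ordered}
    out: list[Labeled] = []
    for (label, bin_lab), n in counts.items():
        _check_label(label)
        b = by_label[bin_lab]
        score = b.lo if b.lo == b.hi else (b.lo + b.hi) / 2
        out.extend([(score, label)] * n)
    return out


# ---------------------------------------------------------------------------
# two-approach union accounting


@dataclass(frozen=True)
class UnionReport:
    """Set arithmetic for combining the two approaches' pair sets, plus
    the cross-tabulation of type assignments over the overlap."""

    n_a: int
    n_b: int
    n_overlap: int
    n_union: int
    overlap_types: Mapping[tuple[str, str], int]

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_overlap": self.n_overlap,
            "n_union": self.n_union,
            "overlap_types": {f"{a}/{b}": n for (a, b), n in sorted(self.overlap_types.items())},
        }


def union_report(
    set_a: Mapping[DiseasePair, str], set_b: Mapping[DiseasePair, str]
) -> UnionReport:
    """Combine two pair-to-type mappings.

    Reports |A|, |B|, |A ∩ B| and |A ∪ B| (inclusion-exclusion holds by
    construction), and for each overlapping pair the (type-in-A,
    type-in-B) combination — e.g. how many tree-derived "Siblings" the
    review had called "Subtypes"."""
    overlap = set(set_a) & set(set_b)
    types: dict[tuple[str, str], int] = {}
    for pair in overlap:
        key = (set_a[pair], set_b[pair])
        types[key] = types.get(key, 0) + 1
    return UnionReport(
        n_a=len(set_a),
        n_b=len(set_b),
        n_overlap=len(overlap),
        n_union=len(set_a) + len(set_b) - len(overlap),
        overlap_types=types,
    )


# ---------------------------------------------------------------------------
# label-table input / output

LABEL_COLUMNS = ["gard_a", "gard_b", "label", "retire_flag_a", "retire_flag_b", "note"]


def load_labels(path: str | Path) -> dict[DiseasePair, str]:
    """Read a curated pair-label TSV into a pair-to-label mapping.

    Pairs in which either member is flagged for retirement (its latest
    prevalence no longer qualifies as rare) are dropped before any
    evaluation, mirroring removal of retired diseases before pairing.
    """
    from .curies import normalize_curie

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise GraphLoadError(f"{path}: missing columns {missing}")
    out: dict[DiseasePair, str] = {}
    for row in df.itertuples(index=False):
        if row.retire_flag_a.lower() == "true" or row.retire_flag_b.lower() == "true":
            continue
        pair = DiseasePair(normalize_curie(row.gard_a), normalize_curie(row.gard_b))
        out[pair] = _check_label(row.label)
    return out


def write_labels(
    labels: Mapping[DiseasePair, str],
    path: str | Path,
    retired: frozenset = frozenset(),
    notes: Optional[Mapping[DiseasePair, str]] = None,
) -> None:
    rows = []
    for pair in sorted(labels):
        rows.append(
            {
                "gard_a": str(pair.a),
                "gard_b": str(pair.b),
                "label": labels[pair],
                "retire_flag_a": str(pair.a in retired),
                "retire_flag_b": str(pair.b in retired),
                "note": (notes or {}).get(pair, ""),
            }
        )
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_metrics(metrics: Metrics, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics.as_dict(), indent=2) + "\n")
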