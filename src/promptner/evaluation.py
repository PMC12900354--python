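"""Exact-match NER evaluation with document-level bootstrap inference.

A model answers each (document, entity type) query with a comma-separated
string of entity names.  Evaluation parses that string into a normalized
entity *set* (lowercase, trimmed, one trailing period stripped, duplicates
collapsed), compares it with the equally normalized gold set by exact string
match, and pools true-positive / prediction / gold counts over documents
into micro precision, recall, and F1 (harmonic mean).

Uncertainty comes from a nonparametric document-level bootstrap: resample
test documents with replacement, recompute the pooled metrics per replicate,
and report the 2.5th/97.5th percentile interval.  Paired comparisons (e.g.
a retrieval-augmented prompt versus its baseline) reuse one shared resample
per replicate in both arms and report the mean difference, its percentile
interval, and a one-sided bootstrap p-value for improvement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus import AnnotatedDocument, EntityType

__all__ = [
    "ParsedOutput",
    "DocCounts",
    "MetricResult",
    "PairedDelta",
    "normalize_entity",
    "parse_model_output",
    "doc_counts",
    "micro_metrics",
    "harmonic_f1",
    "bootstrap_ci",
    "paired_bootstrap",
    "DEFAULT_BOOTSTRAP_REPLICATES",
]

DEFAULT_BOOTSTRAP_REPLICATES = 2000
_NONE_LITERAL = "none"


def normalize_entity(s: str) -> str:
    """Lowercase, trim, and strip one trailing period.

    Deliberately minimal: anything stronger (lemmatization, punctuation
    scrubbing) would silently redefine "exact match".
    """
    s = s.strip().lower()
    if s.endswith("."):
        s = s[:-1].rstrip()
    return s


@dataclass(frozen=True)
class ParsedOutput:
    """Normalized entity set parsed from one raw model answer."""

    doc_id: str
    etype: EntityType
    entities: tuple[str, ...]  # deduplicated, first-occurrence order
    raw_text: str
    parse_warning: bool = False

    @property
    def entity_set(self) -> frozenset[str]:
        return frozenset(self.entities)


def parse_model_output(raw: str, doc_id: str, etype: EntityType) -> ParsedOutput:
    """Parse a raw answer string into a normalized entity set.

    Splits on commas (newlines are tolerated as additional separators but
    flagged with a parse warning), normalizes each item, drops empties and
    the literal ``"none"``, and deduplicates preserving first occurrence.
    Any string parses; there is no failure mode.
    """
    etype = EntityType(etype)
    warning = "\n" in raw.strip()
    pieces = raw.replace("\n", ",").split(",")
    seen: list[str] = []
    for piece in pieces:
        norm = normalize_entity(piece)
        if not norm or norm == _NONE_LITERAL:
            continue
        if norm not in seen:
            seen.append(norm)
    return ParsedOutput(
        doc_id=doc_id, etype=etype, entities=tuple(seen), raw_text=raw,
        parse_warning=warning,
    )


@dataclass(frozen=True)
class DocCounts:
    """Per-document true-positive / prediction / gold set sizes."""

    doc_id: str
    etype: EntityType
    tp: int
    n_pred: int
    n_gold: int

    def __post_init__(self) -> None:
        if not 0 <= self.tp <= min(self.n_pred, self.n_gold):
            raise ValueError(
                f"tp={self.tp} inconsistent with n_pred={self.n_pred}, "
                f"n_gold={self.n_gold}"
            )


def gold_entity_set(doc: AnnotatedDocument, etype: EntityType) -> frozenset[str]:
    """The document's normalized, deduplicated gold strings of one type."""
    return frozenset(normalize_entity(m.surface) for m in doc.mentions_of(etype))


def doc_counts(pred: ParsedOutput, gold: AnnotatedDocument, etype: EntityType) -> DocCounts:
    """Exact-string-match counts for one document and entity type."""
    etype = EntityType(etype)
    if pred.doc_id != gold.doc_id:
        raise ValueError(f"doc_id mismatch: {pred.doc_id!r} vs {gold.doc_id!r}")
    gold_set = gold_entity_set(gold, etype)
    pred_set = pred.entity_set
    return DocCounts(
        doc_id=gold.doc_id,
        etype=etype,
        tp=len(pred_set & gold_set),
        n_pred=len(pred_set),
        n_gold=len(gold_set),
    )


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R); zero when both are zero."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricResult:
    precision: float
    recall: float
    f1: float
    degenerate_denominator: bool = False
    ci_precision: tuple[float, float] | None = None
    ci_recall: tuple[float, float] | None = None
    ci_f1: tuple[float, float] | None = None
    n_replicates: int | None = None
    n_degenerate_replicates: int = 0


def _pooled(counts: Sequence[DocCounts]) -> tuple[float, float, float, bool]:
    tp = sum(c.tp for c in counts)
    n_pred = sum(c.n_pred for c in counts)
    n_gold = sum(c.n_gold for c in counts)
    degenerate = n_pred == 0 or n_gold == 0
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    return p, r, harmonic_f1(p, r), degenerate


def micro_metrics(counts: Sequence[DocCounts]) -> MetricResult:
    """Micro (pooled-count) precision, recall, and F1 over documents."""
    if not counts:
        raise ValueError("cannot compute metrics over an empty collection")
    p, r, f, degenerate = _pooled(counts)
    return MetricResult(precision=p, recall=r, f1=f, degenerate_denominator=degenerate)


def _resample_indices(n: int, n_replicates: int | None, rng: np.random.Generator):
    """Bootstrap index sets: seeded draws, or full enumeration when
    ``n_replicates`` is None (all n**n ordered resamples; tiny n only)."""
    if n_replicates is None:
        yield from itertools.product(range(n), repeat=n)
    else:
        for _ in range(n_replicates):
            yield tuple(rng.integers(0, n, size=n))


def bootstrap_ci(
    counts: Sequence[DocCounts],
    n_replicates: int | None = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
) -> MetricResult:
    """Document-level bootstrap percentile CIs for the pooled metrics.

    ``n_replicates=None`` switches to exhaustive enumeration of all ordered
    resamples (testing aid; feasible only for a handful of documents).
    """
    if len(counts) < 2:
        raise ValueError("bootstrap needs at least 2 documents")
    point = micro_metrics(counts)
    rng = np.random.default_rng(seed)
    reps = {"precision": [], "recall": [], "f1": []}
    degenerate = 0
    for idx in _resample_indices(len(counts), n_replicates, rng):
        p, r, f, deg = _pooled([counts[i] for i in idx])
        degenerate += deg
        reps["precision"].append(p)
        reps["recall"].append(r)
        reps["f1"].append(f)

    def ci(vals: list[float]) -> tuple[float, float]:
        return (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )

    return MetricResult(
        precision=point.precision,
        recall=point.recall,
        f1=point.f1,
        degenerate_denominator=point.degenerate_denominator,
        ci_precision=ci(reps["precision"]),
        ci_recall=ci(reps["recall"]),
        ci_f1=ci(reps["f1"]),
        n_replicates=len(reps["f1"]),
        n_degenerate_replicates=degenerate,
    )


@dataclass(frozen=True)
class PairedDelta:
    metric: str
    mean_delta: float
    ci_low: float
    ci_high: float
    p_one_sided: float


def paired_bootstrap(
    baseline: Sequence[DocCounts],
    variant: Sequence[DocCounts],
    n_replicates: int | None = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
) -> dict[str, PairedDelta]:
    """Paired document-level bootstrap of variant minus baseline.

    One shared resample per replicate drives both arms.  The one-sided
    p-value for improvement uses the add-one convention
    ``p = (1 + #{delta_b <= 0}) / (B + 1)``.
    """
    base_by_id = {c.doc_id: c for c in baseline}
    var_by_id = {c.doc_id: c for c in variant}
    if set(base_by_id) != set(var_by_id):
        raise ValueError("baseline and variant must cover identical doc_id sets")
    ids = [c.doc_id for c in baseline]
    base = [base_by_id[i] for i in ids]
    var = [var_by_id[i] for i in ids]

    rng = np.random.default_rng(seed)
    deltas = {"precision": [], "recall": [], "f1": []}
    for idx in _resample_indices(len(ids), n_replicates, rng):
        bp, br, bf, _ = _pooled([base[i] for i in idx])
        vp, vr, vf, _ = _pooled([var[i] for i in idx])
        deltas["precision"].append(vp - bp)
        deltas["recall"].append(vr - br)
        deltas["f1"].append(vf - bf)

    out: dict[str, PairedDelta] = {}
    for metric, vals in deltas.items():
        arr = np.asarray(vals)
        b = len(arr)
        out[metric] = PairedDelta(
            metric=metric,
            mean_delta=float(arr.mean()),
            ci_low=float(np.percentile(arr, 2.5)),
            ci_high=float(np.percentile(arr, 97.5)),
            p_one_sided=float((1 + int((arr <= 0).sum())) / (b + 1)),
        )
    return out
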