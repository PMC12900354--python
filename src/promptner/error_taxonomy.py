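"""Six-way error taxonomy via greedy token-overlap alignment.

Beyond exact-match metrics, each model output for an entity-type task is
aligned one-to-one with the document's gold mentions (across *all four*
types, so that type confusions are observable) by greedy case-insensitive
token overlap: predictions are processed in output order, each taking the
still-available gold span with the highest overlap (> 0), ties going to
annotation order.  Every aligned or unmatched item falls into exactly one
category:

* ``correct``        — strings equal, types equal
* ``boundary``       — overlap > 0, strings differ, types equal
* ``type``           — strings equal, types differ
* ``boundary_type``  — overlap > 0, strings differ, types differ
* ``spurious``       — prediction matched no gold span
* ``missed``         — task-type gold matched no prediction

The spurious/sign cross-check quantifies how much symptom overgeneration is
really sign/symptom boundary confusion: the fraction of spurious symptom
strings that exactly match a gold sign mention in the same document.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .corpus import AnnotatedDocument, EntityType
from .evaluation import ParsedOutput, normalize_entity

__all__ = [
    "Category",
    "AlignmentRecord",
    "TaxonomyDistribution",
    "token_overlap",
    "greedy_align",
    "classify_alignment",
    "taxonomy_distribution",
    "spurious_crosscheck",
    "align_document",
]


class Category(str, Enum):
    CORRECT = "correct"
    BOUNDARY = "boundary"
    TYPE = "type"
    BOUNDARY_TYPE = "boundary_type"
    SPURIOUS = "spurious"
    MISSED = "missed"


def _tokens(s: str) -> frozenset[str]:
    toks = []
    for t in s.lower().split():
        t = t.strip(string.punctuation)
        if t:
            toks.append(t)
    return frozenset(toks)


def token_overlap(a: str, b: str) -> int:
    """|tokens(a) ∩ tokens(b)| with case-insensitive, edge-punctuation-stripped
    whitespace tokens.  Symmetric."""
    return len(_tokens(a) & _tokens(b))


@dataclass(frozen=True)
class AlignmentRecord:
    """One prediction/gold pairing, or an unmatched item."""

    doc_id: str
    task_type: EntityType
    prediction: str | None  # normalized predicted string
    gold: str | None  # normalized gold string
    gold_type: EntityType | None
    overlap: int
    category: Category

    def __post_init__(self) -> None:
        if self.prediction is None and self.gold is None:
            raise ValueError("record must carry a prediction, a gold span, or both")
        if self.prediction is not None and self.gold is not None and self.overlap <= 0:
            raise ValueError("matched records require overlap > 0")


def classify_alignment(
    prediction: str | None,
    gold: str | None,
    gold_type: EntityType | None,
    task_type: EntityType,
    overlap: int,
) -> Category:
    """Deterministic category for one aligned or unmatched item."""
    task_type = EntityType(task_type)
    if prediction is None:
        return Category.MISSED
    if gold is None:
        return Category.SPURIOUS
    if overlap <= 0:
        raise ValueError("aligned pairs must share at least one token")
    same_string = prediction == gold
    same_type = EntityType(gold_type) == task_type
    if same_string and same_type:
        return Category.CORRECT
    if same_string:
        return Category.TYPE
    if same_type:
        return Category.BOUNDARY
    return Category.BOUNDARY_TYPE


def greedy_align(
    predictions: Sequence[str],
    gold_pool: Sequence[tuple[str, EntityType]],
    task_type: EntityType,
    doc_id: str = "",
) -> list[AlignmentRecord]:
    """Greedy one-to-one alignment of predictions to the document's gold spans.

    ``predictions`` are normalized strings in model output order;
    ``gold_pool`` holds the document's (normalized string, type) golds of all
    four types in annotation order.  Each prediction takes the first
    still-available gold with maximal token overlap > 0.  Unmatched
    predictions become spurious; unmatched golds *of the task type* become
    missed (a sign gold left over during the symptom task is not a symptom
    miss).
    """
    task_type = EntityType(task_type)
    available = list(range(len(gold_pool)))
    records: list[AlignmentRecord] = []
    for pred in predictions:
        best_idx, best_ov = None, 0
        for gi in available:
            ov = token_overlap(pred, gold_pool[gi][0])
            if ov > best_ov:  # strict: ties keep the earlier (annotation-order) gold
                best_idx, best_ov = gi, ov
        if best_idx is None:
            records.append(
                AlignmentRecord(
                    doc_id=doc_id, task_type=task_type, prediction=pred,
                    gold=None, gold_type=None, overlap=0,
                    category=Category.SPURIOUS,
                )
            )
        else:
            available.remove(best_idx)
            g, gt = gold_pool[best_idx]
            records.append(
                AlignmentRecord(
                    doc_id=doc_id, task_type=task_type, prediction=pred,
                    gold=g, gold_type=gt, overlap=best_ov,
                    category=classify_alignment(pred, g, gt, task_type, best_ov),
                )
            )
    for gi in available:
        g, gt = gold_pool[gi]
        if EntityType(gt) == task_type:
            records.append(
                AlignmentRecord(
                    doc_id=doc_id, task_type=task_type, prediction=None,
                    gold=g, gold_type=gt, overlap=0, category=Category.MISSED,
                )
            )
    return records


def align_document(
    pred: ParsedOutput, gold: AnnotatedDocument, cross_type: bool = True
) -> list[AlignmentRecord]:
    """Convenience wrapper: align one parsed output against one document.

    By default the gold pool spans all four entity types (normalized,
    deduplicated per (string, type) in annotation order) so type confusions
    are attributable.  ``cross_type=False`` restricts the pool to the task
    type — the reading under which a symptom output copying a sign mention
    stays *spurious*, which is what the spurious/sign cross-check assesses.
    """
    if pred.doc_id != gold.doc_id:
        raise ValueError(f"doc_id mismatch: {pred.doc_id!r} vs {gold.doc_id!r}")
    pool: list[tuple[str, EntityType]] = []
    seen: set[tuple[str, EntityType]] = set()
    for m in gold.mentions:
        if not cross_type and m.etype != pred.etype:
            continue
        key = (normalize_entity(m.surface), m.etype)
        if key not in seen:
            seen.add(key)
            pool.append(key)
    return greedy_align(pred.entities, pool, pred.etype, doc_id=gold.doc_id)


@dataclass(frozen=True)
class TaxonomyDistribution:
    counts: Mapping[Category, int]
    proportions: Mapping[Category, float]
    denominator: int  # matched pairs + spurious + missed


def taxonomy_distribution(records: Sequence[AlignmentRecord]) -> TaxonomyDistribution:
    """Category counts and proportions over matched + spurious + missed items."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    counts = Counter(r.category for r in records)
    full = {c: counts.get(c, 0) for c in Category}
    denom = sum(full.values())
    return TaxonomyDistribution(
        counts=full,
        proportions={c: v / denom for c, v in full.items()},
        denominator=denom,
    )


def spurious_crosscheck(
    spurious_records: Iterable[AlignmentRecord],
    sign_golds_by_doc: Mapping[str, Iterable[str]],
) -> tuple[int, int, float | None]:
    """How many spurious symptom outputs exactly match a same-document sign?

    Returns ``(n_matching, n_spurious, percentage)`` with the percentage
    rounded to one decimal place, or ``None`` when there are no spurious
    records to assess.
    """
    normalized_signs = {
        doc_id: {normalize_entity(s) for s in signs}
        for doc_id, signs in sign_golds_by_doc.items()
    }
    numerator = denominator = 0
    for rec in spurious_records:
        if rec.category is not Category.SPURIOUS:
            raise ValueError("spurious_crosscheck expects spurious records only")
        denominator += 1
        if rec.prediction in normalized_signs.get(rec.doc_id, set()):
            numerator += 1
    pct = round(100.0 * numerator / denominator, 1) if denominator else None
    return numerator, denominator, pct
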