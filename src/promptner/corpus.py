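"""Annotated-corpus I/O for rare-disease NER experiments.

A corpus is an ordered collection of documents, each a plain-text clinical
report carrying manually annotated entity mentions of four types: rare
disease, disease, sign, and symptom.  Documents can be read from a JSONL
container (one document per line) or from BRAT-style standoff ``.txt`` /
``.ann`` pairs, split into train/validation/test subsets, and summarized
into per-type, per-split mention count tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EntityType",
    "Split",
    "EntityMention",
    "AnnotatedDocument",
    "AnnotatedCorpus",
    "read_jsonl_corpus",
    "write_jsonl_corpus",
    "read_brat_document",
    "split_corpus",
    "entity_count_table",
    "flatten_labels",
    "EMPTY_LABEL",
]

#: Literal emitted when a document has no mentions of the requested type,
#: mirroring the output-format instruction "If there is no (entity), output 'none'".
EMPTY_LABEL = "none"


class EntityType(str, Enum):
    """The four annotated entity types of the rare-disease corpus."""

    RARE_DISEASE = "rare_disease"
    DISEASE = "disease"
    SIGN = "sign"
    SYMPTOM = "symptom"


class Split(str, Enum):
    TRAIN = "train"
    VAL = "val"
    TEST = "test"


@dataclass(frozen=True)
class EntityMention:
    """One annotated surface span.

    ``char_start``/``char_end`` are optional 0-based half-open character
    offsets into the document text; when present the slice must reproduce
    ``surface`` exactly.
    """

    surface: str
    etype: EntityType
    char_start: int | None = None
    char_end: int | None = None

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise ValueError("mention surface must be non-empty after trimming")
        object.__setattr__(self, "etype", EntityType(self.etype))
        if (self.char_start is None) != (self.char_end is None):
            raise ValueError("char_start and char_end must be given together")


@dataclass
class AnnotatedDocument:
    """A document text with its annotated entity mentions."""

    doc_id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    split: Split | None = None

    def __post_init__(self) -> None:
        if self.split is not None:
            self.split = Split(self.split)
        for m in self.mentions:
            if m.char_start is not None:
                span = self.text[m.char_start : m.char_end]
                if span != m.surface:
                    raise ValueError(
                        f"doc {self.doc_id!r}: offset slice {span!r} does not "
                        f"match surface {m.surface!r}"
                    )

    def mentions_of(self, etype: EntityType) -> list[EntityMention]:
        etype = EntityType(etype)
        return [m for m in self.mentions if m.etype == etype]


@dataclass
class AnnotatedCorpus:
    """Ordered list of annotated documents with unique ids."""

    documents: list[AnnotatedDocument]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("doc_id values must be unique within a corpus")

    @property
    def n(self) -> int:
        return len(self.documents)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.documents)

    def __getitem__(self, i):
        return self.documents[i]

    def subset(self, split: Split) -> "AnnotatedCorpus":
        split = Split(split)
        return AnnotatedCorpus([d for d in self.documents if d.split == split])


def _mention_to_json(m: EntityMention) -> dict:
    d: dict = {"surface": m.surface, "etype": m.etype.value}
    if m.char_start is not None:
        d["char_start"] = m.char_start
        d["char_end"] = m.char_end
    return d


def write_jsonl_corpus(corpus: AnnotatedCorpus, path: str | Path) -> int:
    """Write one JSON object per document; returns the document count."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            rec: dict = {
                "doc_id": doc.doc_id,
                "text": doc.text,
                "mentions": [_mention_to_json(m) for m in doc.mentions],
            }
            if doc.split is not None:
                rec["split"] = doc.split.value
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return corpus.n


def read_jsonl_corpus(path: str | Path) -> AnnotatedCorpus:
    """Read a JSONL corpus, preserving document order.

    Raises ``ValueError`` naming the line number on a malformed line, and
    naming the doc_id when stored offsets do not reproduce the surface.
    """
    path = Path(path)
    docs: list[AnnotatedDocument] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                mentions = [
                    EntityMention(
                        surface=m["surface"],
                        etype=EntityType(m["etype"]),
                        char_start=m.get("char_start"),
                        char_end=m.get("char_end"),
                    )
                    for m in rec.get("mentions", [])
                ]
                docs.append(
                    AnnotatedDocument(
                        doc_id=rec["doc_id"],
                        text=rec["text"],
                        mentions=mentions,
                        split=rec.get("split"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"{path}: invalid document on line {lineno} "
                    f"(doc_id={rec.get('doc_id')!r}): {exc}"
                ) from exc
    return AnnotatedCorpus(docs)


#: Default mapping from BRAT type labels to the four entity types.
DEFAULT_BRAT_TYPE_MAP: Mapping[str, EntityType] = {
    "RAREDISEASE": EntityType.RARE_DISEASE,
    "DISEASE": EntityType.DISEASE,
    "SIGN": EntityType.SIGN,
    "SYMPTOM": EntityType.SYMPTOM,
}


def read_brat_document(
    text_path: str | Path,
    ann_path: str | Path,
    type_map: Mapping[str, EntityType] | None = None,
    doc_id: str | None = None,
) -> AnnotatedDocument:
    """Read one BRAT standoff pair (``.txt`` + ``.ann``).

    Only contiguous text-bound annotations ("T" lines of the form
    ``T<id>\\t<TYPE> <start> <end>\\t<surface>``) are accepted; discontinuous
    spans (offsets containing ``;``) are rejected rather than merged, because
    surface-string evaluation never defines their semantics.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    type_map = dict(DEFAULT_BRAT_TYPE_MAP if type_map is None else type_map)
    text = text_path.read_text(encoding="utf-8")
    mentions: list[EntityMention] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or not line.startswith("T"):
            continue  # relation/event/note lines are ignored
        try:
            _tid, type_and_span, surface = line.split("\t", 2)
            type_label, span = type_and_span.split(" ", 1)
        except ValueError as exc:
            raise ValueError(f"{ann_path}: malformed annotation on line {lineno}") from exc
        if ";" in span:
            raise ValueError(
                f"{ann_path}: discontinuous span on line {lineno} is not supported"
            )
        start_s, end_s = span.split()
        start, end = int(start_s), int(end_s)
        if type_label not in type_map:
            raise ValueError(
                f"{ann_path}: unknown entity type label {type_label!r} on line "
                f"{lineno}; provide a type_map entry for it"
            )
        if text[start:end] != surface:
            raise ValueError(
                f"{ann_path}: line {lineno}: text slice {text[start:end]!r} "
                f"does not match annotated surface {surface!r}"
            )
        mentions.append(
            EntityMention(surface=surface, etype=type_map[type_label],
                          char_start=start, char_end=end)
        )
    return AnnotatedDocument(
        doc_id=doc_id or text_path.stem, text=text, mentions=mentions
    )


def split_corpus(
    corpus: AnnotatedCorpus,
    fractions: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    preserve_existing: bool = False,
) -> AnnotatedCorpus:
    """Assign train/val/test labels by a seeded shuffle.

    Split sizes are the fractions times N rounded to nearest (half away from
    zero), with any residual absorbed by the largest split so that sizes sum
    to N; on 1,041 documents at 70/10/20 this yields 729/104/208.
    """
    if corpus.n == 0:
        raise ValueError("cannot split an empty corpus")
    fractions = [float(f) for f in fractions]
    if len(fractions) != 3:
        raise ValueError("fractions must have exactly three entries (train, val, test)")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    n = corpus.n
    sizes = [int(np.floor(f * n + 0.5)) for f in fractions]
    residual = n - sum(sizes)
    sizes[int(np.argmax(fractions))] += residual
    if min(sizes) < 0:  # pathological tiny-N case after absorption
        raise ValueError("fractions produce a negative split size")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels: list[Split] = [Split.TRAIN] * sizes[0] + [Split.VAL] * sizes[1] + [Split.TEST] * sizes[2]

    out = []
    for pos, doc in zip(np.argsort(order), corpus):
        # argsort(order) gives each document's rank in the shuffled order
        if preserve_existing and doc.split is not None:
            out.append(doc)
        else:
            out.append(replace(doc, split=labels[pos]))
    return AnnotatedCorpus(out)


def entity_count_table(corpus: AnnotatedCorpus) -> pd.DataFrame:
    """Per (entity type x split) mention counts with row/column totals.

    Counts are multiset counts (duplicate surfaces included).  Every document
    must carry a split label.
    """
    for doc in corpus:
        if doc.split is None:
            raise ValueError(f"document {doc.doc_id!r} has no split label")
    etypes = [e.value for e in EntityType]
    splits = [s.value for s in Split]
    table = pd.DataFrame(0, index=etypes, columns=splits, dtype=int)
    for doc in corpus:
        for m in doc.mentions:
            table.loc[m.etype.value, doc.split.value] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def flatten_labels(doc: AnnotatedDocument, etype: EntityType) -> str:
    """Flatten a document's mentions of one type into the answer string.

    Mentions are lowercased and joined by ``", "`` in annotation order with
    duplicates retained; a document with no mentions of the type yields the
    literal ``"none"``.
    """
    surfaces = [m.surface.lower() for m in doc.mentions_of(etype)]
    return ", ".join(surfaces) if surfaces else EMPTY_LABEL
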