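"""Retrieval-augmented knowledge index.

The knowledge corpus is a list of (disease name, definition snippet) entries
— the structure of an Orphanet-style alignment corpus.  Each snippet is
embedded once; at inference time the K snippets nearest to the inquiry
embedding (Euclidean distance) are prepended to the prompt.  Minimizing the
summed distance of a size-K subset is equivalent to taking the K nearest
entries, which keeps retrieval a single argsort.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .cost_model import count_tokens

__all__ = [
    "KnowledgeEntry",
    "KnowledgeIndex",
    "read_knowledge_corpus",
    "build_index",
    "retrieve_topk",
    "format_snippet",
    "DEFAULT_K_GRID",
]

#: Default grid of snippet counts; larger K tends to add semantic noise.
DEFAULT_K_GRID = (1, 2)


@dataclass(frozen=True)
class KnowledgeEntry:
    name: str
    snippet: str
    token_length: int
    embedding: np.ndarray

    def __post_init__(self) -> None:
        if not self.snippet.strip():
            raise ValueError("snippet must be non-empty")
        if self.token_length < 1:
            raise ValueError("token_length must be >= 1")


@dataclass(frozen=True)
class KnowledgeIndex:
    entries: tuple[KnowledgeEntry, ...]
    dim: int
    n_rejected: int = 0  # empty-snippet records dropped during build

    @property
    def t(self) -> int:
        """Number of indexed entries."""
        return len(self.entries)

    @property
    def median_token_length(self) -> float:
        return float(np.median([e.token_length for e in self.entries]))


def read_knowledge_corpus(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, definition) records from JSONL or 2-column TSV."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    if path.suffix.lower() in {".tsv", ".txt"}:
        with path.open("r", encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if row:
                    records.append((row[0], row[1] if len(row) > 1 else ""))
    else:
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    records.append((rec["name"], rec["snippet"]))
    return records


def build_index(
    records: Iterable[tuple[str, str]],
    embedder: Callable[[str], np.ndarray],
    tokenizer: Callable[[str], int] | None = None,
) -> KnowledgeIndex:
    """Embed and token-count every record.

    Records with empty snippets are rejected (counted in ``n_rejected``).
    Reproducible given a deterministic embedder.
    """
    tokenizer = tokenizer or count_tokens
    entries: list[KnowledgeEntry] = []
    rejected = 0
    for name, snippet in records:
        if not snippet.strip():
            rejected += 1
            continue
        vec = np.asarray(embedder(snippet), dtype=float)
        entries.append(
            KnowledgeEntry(
                name=name,
                snippet=snippet,
                token_length=max(1, int(tokenizer(snippet))),
                embedding=vec,
            )
        )
    if not entries:
        raise ValueError("knowledge corpus has no usable entries")
    dims = {e.embedding.shape for e in entries}
    if len(dims) != 1:
        raise ValueError(f"embedder returned inconsistent dimensions: {dims}")
    return KnowledgeIndex(entries=tuple(entries), dim=entries[0].embedding.shape[0],
                          n_rejected=rejected)


def retrieve_topk(
    inquiry_vec: np.ndarray, index: KnowledgeIndex, k: int
) -> list[KnowledgeEntry]:
    """The K entries nearest the inquiry, ascending by distance, ties by entry order."""
    if not 0 <= k <= index.t:
        raise ValueError(f"K must be in [0, {index.t}], got {k}")
    if k == 0:
        return []
    inquiry_vec = np.asarray(inquiry_vec, dtype=float)
    mat = np.stack([e.embedding for e in index.entries])
    dists = np.linalg.norm(mat - inquiry_vec[None, :], axis=1)
    order = sorted(range(index.t), key=lambda i: (dists[i], i))[:k]
    return [index.entries[i] for i in order]


def format_snippet(entry: KnowledgeEntry) -> str:
    """Canonical one-line prompt rendering of a knowledge entry."""
    return f"{entry.name}: {entry.snippet}"
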