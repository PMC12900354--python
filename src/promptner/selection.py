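"""In-context exemplar selection over an embedding space.

Three strategies for choosing the k demonstration pairs prepended to a
few-shot prompt:

* **Inquiry-Random** — k training documents drawn uniformly without
  replacement, independent of semantic similarity.
* **Inquiry-KNN** — the k training documents nearest to the inquiry in
  embedding space (Euclidean distance), one set per inquiry.
* **Cluster-KNN** — k-means-partition the *test* set into C clusters; for
  each cluster pick the k training documents with the smallest mean distance
  to the cluster's members.  All inquiries in a cluster share one exemplar
  set, so at most C*k distinct training documents ever need labels.

Distance ties are broken by ascending doc_id, making every selection a pure
function of its inputs (invariant to pool ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .corpus import AnnotatedDocument, EntityType, flatten_labels

__all__ = [
    "SelectionMethod",
    "ExemplarSet",
    "ClusterAssignment",
    "pairwise_distance",
    "select_random",
    "select_inquiry_knn",
    "kmeans_clusters",
    "select_cluster_knn",
    "DEFAULT_K_GRID",
]

#: Default grid of shot counts swept in few-shot experiments.
DEFAULT_K_GRID = (1, 2, 4, 6, 8, 10, 12, 14, 16)


class SelectionMethod(str, Enum):
    INQUIRY_RANDOM = "inquiry_random"
    INQUIRY_KNN = "inquiry_knn"
    CLUSTER_KNN = "cluster_knn"


@dataclass(frozen=True)
class ExemplarSet:
    """k (input text, flattened label) demonstration pairs with provenance."""

    pairs: tuple[tuple[str, str], ...]
    method: SelectionMethod
    doc_ids: tuple[str, ...]
    cluster_id: int | None = None
    n_clusters: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError("exemplar doc_ids must be distinct")
        if len(self.doc_ids) != len(self.pairs):
            raise ValueError("doc_ids and pairs must have equal length")

    @property
    def k(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ClusterAssignment:
    """k-means partition of the test set in embedding space."""

    n_clusters: int
    assignment: Mapping[str, int]  # test doc_id -> cluster index
    centroids: np.ndarray  # (C, d)

    def members(self, j: int) -> list[str]:
        return [i for i, c in self.assignment.items() if c == j]


def pairwise_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance ||u - v||2 between two embedding vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def _pairs_for(docs: Sequence[AnnotatedDocument], etype: EntityType):
    return tuple((d.text, flatten_labels(d, etype)) for d in docs)


def select_random(
    pool: Sequence[AnnotatedDocument],
    etype: EntityType,
    k: int,
    seed: int,
) -> ExemplarSet:
    """k training documents uniformly at random, without replacement."""
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    chosen = [pool[i] for i in idx]
    return ExemplarSet(
        pairs=_pairs_for(chosen, etype),
        method=SelectionMethod.INQUIRY_RANDOM,
        doc_ids=tuple(d.doc_id for d in chosen),
    )


def _ranked_indices(dists: np.ndarray, doc_ids: Sequence[str]) -> list[int]:
    """Indices sorted by (distance, doc_id) — the canonical tie rule."""
    return sorted(range(len(doc_ids)), key=lambda i: (dists[i], doc_ids[i]))


def select_inquiry_knn(
    inquiry_vec: np.ndarray,
    pool: Sequence[AnnotatedDocument],
    pool_vecs: np.ndarray,
    etype: EntityType,
    k: int,
) -> ExemplarSet:
    """The k pool documents nearest to the inquiry, ordered by ascending distance."""
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    pool_vecs = np.asarray(pool_vecs, dtype=float)
    inquiry_vec = np.asarray(inquiry_vec, dtype=float)
    if pool_vecs.shape[0] != len(pool):
        raise ValueError("pool_vecs rows must align with pool documents")
    if pool_vecs.shape[1] != inquiry_vec.shape[0]:
        raise ValueError("embedding dimension mismatch")
    dists = np.linalg.norm(pool_vecs - inquiry_vec[None, :], axis=1)
    order = _ranked_indices(dists, [d.doc_id for d in pool])[:k]
    chosen = [pool[i] for i in order]
    return ExemplarSet(
        pairs=_pairs_for(chosen, etype),
        method=SelectionMethod.INQUIRY_KNN,
        doc_ids=tuple(d.doc_id for d in chosen),
    )


def kmeans_clusters(
    test_ids: Sequence[str],
    test_vecs: np.ndarray,
    n_clusters: int,
    seed: int,
) -> ClusterAssignment:
    """Partition the test set into C clusters by k-means (k-means++ seeding).

    Typical values of C are 32 or 64; the partition is computed once per test
    set and shared across entity types.
    """
    test_vecs = np.asarray(test_vecs, dtype=float)
    n = len(test_ids)
    if not 0 < n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=10,
        tol=1e-6,
        random_state=seed,
    ).fit(test_vecs)
    assignment = {i: int(c) for i, c in zip(test_ids, km.labels_)}
    return ClusterAssignment(
        n_clusters=n_clusters, assignment=assignment, centroids=km.cluster_centers_
    )


def select_cluster_knn(
    assignment: ClusterAssignment,
    pool: Sequence[AnnotatedDocument],
    pool_vecs: np.ndarray,
    test_vecs: Mapping[str, np.ndarray],
    etype: EntityType,
    k: int,
) -> dict[int, ExemplarSet]:
    """Per cluster, the k training documents with smallest mean distance to
    the cluster's members; every inquiry in the cluster shares the set.
    """
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    pool_vecs = np.asarray(pool_vecs, dtype=float)
    doc_ids = [d.doc_id for d in pool]
    out: dict[int, ExemplarSet] = {}
    for j in range(assignment.n_clusters):
        member_ids = assignment.members(j)
        if not member_ids:
            raise ValueError(f"cluster {j} is empty; cannot average over zero members")
        member_mat = np.asarray([test_vecs[i] for i in member_ids], dtype=float)
        # mean over cluster members of the distance to each training doc
        dists = np.linalg.norm(
            pool_vecs[:, None, :] - member_mat[None, :, :], axis=2
        ).mean(axis=1)
        order = _ranked_indices(dists, doc_ids)[:k]
        chosen = [pool[i] for i in order]
        out[j] = ExemplarSet(
            pairs=_pairs_for(chosen, etype),
            method=SelectionMethod.CLUSTER_KNN,
            doc_ids=tuple(d.doc_id for d in chosen),
            cluster_id=j,
            n_clusters=assignment.n_clusters,
        )
    return out
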