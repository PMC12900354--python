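"""Compare the three in-context exemplar selection strategies.

Inquiry-KNN picks each test document's nearest training neighbours in
embedding space; Cluster-KNN partitions the test set with k-means and gives
every member of a cluster the same exemplar set (cheaper to label);
Inquiry-Random ignores similarity entirely.
"""

import numpy as np

from promptner import (
    CorpusSpec,
    EntityType,
    Split,
    generate_corpus,
    kmeans_clusters,
    mock_embed,
    select_cluster_knn,
    select_inquiry_knn,
    select_random,
    split_corpus,
)

corpus, _ = generate_corpus(CorpusSpec(n_docs=120, seed=3))
corpus = split_corpus(corpus, seed=3)
train = corpus.subset(Split.TRAIN).documents
test = corpus.subset(Split.TEST).documents

dim = 128
train_vecs = np.stack([mock_embed(d.text, d=dim, seed=3) for d in train])
test_vecs = {d.doc_id: mock_embed(d.text, d=dim, seed=3) for d in test}
k = 4

rand = select_random(train, EntityType.RARE_DISEASE, k, seed=3)
knn_sets = {
    d.doc_id: select_inquiry_knn(test_vecs[d.doc_id], train, train_vecs,
                                 EntityType.RARE_DISEASE, k)
    for d in test
}
assignment = kmeans_clusters([d.doc_id for d in test],
                             np.stack([test_vecs[d.doc_id] for d in test]),
                             n_clusters=4, seed=3)
cluster_sets = select_cluster_knn(assignment, train, train_vecs, test_vecs,
                                  EntityType.RARE_DISEASE, k)

knn_distinct = set().union(*(s.doc_ids for s in knn_sets.values()))
cluster_distinct = set().union(*(s.doc_ids for s in cluster_sets.values()))
print(f"random selection (one set):      {rand.doc_ids}")
print(f"inquiry-KNN distinct exemplars:  {len(knn_distinct)} across {len(test)} queries")
print(f"cluster-KNN distinct exemplars:  {len(cluster_distinct)} "
      f"(<= C*k = {assignment.n_clusters * k})")
# Cluster-KNN needs far fewer distinct labeled examples than per-query KNN —
# the labeling-cost advantage that makes it attractive when annotation is
# the bottleneck.
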