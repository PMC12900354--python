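# Methods

This note records the models and procedures promptner implements, the
defaults it ships, and the design choices made where more than one
reasonable convention exists.

## Corpus model

A corpus is an ordered list of documents `(x_i, Y_i)`, each `Y_i` a list of
typed surface mentions over the four-type inventory {rare disease, disease,
sign, symptom}. Character offsets, when present, are 0-based half-open and
must reproduce the surface exactly; BRAT standoff input accepts contiguous
text-bound annotations only — discontinuous spans are rejected rather than
merged, because surface-string evaluation gives them no defined semantics.
Duplicate mentions are preserved in storage and counting; deduplication
happens only where evaluation's set semantics require it.

`split_corpus` rounds `fraction × N` to nearest (half away from zero) and
absorbs the residual into the largest split, which maps 1,041 documents at
70/10/20 onto 729/104/208. Whether a real corpus was split randomly or by
stratification is generally unknowable from the data, so the loader honors
stored split labels and only synthesizes splits on request.

`flatten_labels` joins a document's mentions of one type with `", "` in
annotation order, lowercased, and emits the literal `none` when empty —
matching the exemplar and output-format conventions used in the prompts, in
which demonstrated outputs are lowercase regardless of source casing.

## Prompt assembly

Segment order is fixed: task description, output format, optional task
guidance, optional disambiguation rule, optional exemplar block, optional
snippet block, inquiry (prefixed by the input prefix). In the combined
few-shot + retrieval mode the exemplar block precedes the snippet block.
The inter-segment separator is a single blank line — the exact joining
whitespace is not dictated by any convention, so one canonical choice is
made and recorded; token counts inherit its reproducibility. Default
component texts ship as a YAML data file and are overridable. Prompts are
modeled as a single user message; chat-role scaffolding beyond that is out
of scope.

An explicitly empty exemplar set or snippet list is an error: zero-shot is
expressed by omission so that condition bookkeeping can never silently
conflate modes.

## Exemplar selection

Similarity is Euclidean distance between embeddings (default dimension
3072, configurable; every test and experiment here uses the deterministic
mock embedder described below). Distance ties are broken by ascending
doc_id, making all selections pure functions of their inputs and invariant
to pool ordering. k-means uses scikit-learn with k-means++ seeding, a fixed
random state, and tolerance 1e-6; the partition is computed once per test
set and shared across entity types, since nothing in the task makes the
geometry type-dependent. The default shot grid is
{1, 2, 4, 6, 8, 10, 12, 14, 16}; cluster counts of interest are 32 and 64
at realistic test-set sizes.

Cluster-KNN reduces to inquiry-KNN when a cluster has a single member, and
to ranking by mean distance to the whole test set when C = 1 — both are
asserted as properties.

## Retrieval augmentation

The knowledge index embeds each (name, definition) entry once and counts
its tokens with the cost model's tokenizer (recorded in metadata, since the
tokenizer that produced any published snippet-length statistics is
generally unstated). Retrieval takes the K nearest entries; minimizing the
summed distance of a size-K subset is provably the same thing, and a test
verifies the equivalence by subset enumeration. Snippets enter the prompt
as `name: snippet` lines — the per-snippet layout inside the block is not
otherwise constrained, so one documented choice is made. The default K grid
is {1, 2}; larger K tends to add semantic noise rather than signal.

## Generation contract and mocks

A backend is anything with a `complete(request) -> str`. The scripted mock
answers from a `(doc_id, entity_type)` table and records every prompt it
receives; the echo-gold mock returns `flatten_labels` output, giving the
framework its global identity test (exact P = R = F1 = 1.0 end to end); the
corruption backend serves pre-computed corrupted outputs. A thin
OpenAI-compatible HTTP adapter (stdlib urllib, temperature 0, three retries
with exponential backoff) exists for live runs but is exercised nowhere in
the tests. Input token counts are always computed locally so cost
accounting does not depend on backend-reported usage.

Fine-tuning is a hosted-service action: the package exports its JSONL input
(chat-message layout by default, prompt/completion behind a flag), one
record per (document, entity type) with the fully assembled basic+advanced
prompt and the flattened labels, and stops there.

## Evaluation

Normalization is deliberately minimal — lowercase, trim, strip one
trailing period — because anything stronger would redefine "exact match".
Both prediction and gold are deduplicated to sets per document; metrics are
micro (pooled counts), so the bootstrap can recompute TP/FP/FN per
replicate. A zero denominator yields metric 0 with a degenerate flag rather
than NaN. The document-level bootstrap defaults to B = 2000 with percentile
(2.5, 97.5) intervals; `n_replicates=None` switches to exhaustive
enumeration of all ordered resamples, which is what the tests compare
against on 3 documents. The paired bootstrap drives both arms with one
shared resample per replicate and reports the one-sided improvement p-value
with the add-one convention `p = (1 + #{Δ_b ≤ 0}) / (B + 1)`, which avoids
p = 0 at finite B.

## Error taxonomy

Alignment is greedy and one-to-one: predictions in model output order, each
taking the still-available gold span with the highest token overlap (> 0),
ties to annotation order. Tokens are lowercased whitespace tokens with edge
punctuation stripped. By default the gold pool spans all four entity types
of the document, because the type and boundary+type categories are
undefined otherwise; misses are nonetheless counted against golds of the
task type only, so a sign gold left over during the symptom task is not a
symptom miss. Proportions are reported over matched + spurious + missed
items.

One tension is worth recording: under the all-types pool, a symptom output
that copies a sign mention aligns to that sign gold and is classified
*type*, not spurious — yet the sign/symptom confusion statistic is defined
over spurious symptom outputs. `align_document` therefore exposes
`cross_type=False`, restricting the pool to the task type; the cross-check
pipeline uses that reading, and the audit trail keeps enough per-record
data to re-run either way.

## Cost model

Cents per query = tokens × rate × 100 / 1e6, rate defaulting to $5 per
million input tokens; output tokens are ignored as negligible for
list-valued NER answers. The default tokenizer splits on whitespace; any
callable text → token list can be plugged in, and outputs record which one
was used.

The exponential fit holds F0 at the observed zero-shot F1 (anchoring the
curve and stabilizing a two-parameter fit on short k grids), estimates λ on
the log scale to enforce positivity, and uses Levenberg–Marquardt least
squares (ftol 1e-10, generous iteration cap). Fits are flagged invalid on
optimizer failure, λ at numerical bounds, or a plateau at or below the
baseline — the signature of a series that does not rise monotonically, for
which the LOESS smoother is the intended fallback. RMSE and pseudo-R²
(1 − SSE/SST about the mean observed F1) accompany every fit;
Δc95 = Δc50 · log 20 / log 2 holds identically and is asserted as such.

LOESS is implemented directly because the predict-at-arbitrary-x contract
is needed: neighborhood = ceil(span·n) nearest points, tri-cube weights
over the neighborhood's maximum distance, weighted degree-1 least squares,
prediction = local intercept. It reproduces statsmodels' LOWESS exactly at
training abscissae when span·n is integral (the two differ in neighborhood
rounding otherwise), and that agreement is a test. Span defaults to 0.75.

Bootstrap bands resample documents once per replicate across all k
conditions jointly, recompute pooled F1 per condition, refit the smoother,
and take pointwise percentile envelopes on a fixed cost grid; failed
replicate fits are dropped and counted.

## Synthetic data

The generator emulates the *structure* of an expert-annotated rare-disease
corpus, not its language: filler-token documents (60–200 tokens) with
two-token mention surfaces spliced in verbatim at word boundaries. Defaults
are 1,041 documents and per-document Poisson mention means 5.0 / 2.3 / 5.1 /
0.4 for rare disease / disease / sign / symptom — the real corpus's
per-type totals divided by its document count, preserving the long-tail
imbalance and symptom sparsity. Per-type vocabularies (100 surfaces each,
10 adjectives × 10 nouns) are token-disjoint across types and drawn without
replacement within a (document, type), which keeps corruption ground truth
unambiguous: a type-confused emission can only ever align to its own gold,
and per-document gold sets equal mention counts.

The corruption channel is mention-level i.i.d. — miss with p_miss, boundary
drift (drop one token) with p_boundary, emission under a different
entity-type task with p_type, else verbatim — plus Poisson(spurious_rate)
spurious strings per (document, task) built from a token-disjoint noise
vocabulary, with an explicit fraction of symptom-task spurious strings
copied from same-document sign mentions. Exact-string emissions are placed
before boundary-corrupted ones in the output order so that greedy alignment
lets every exact emission claim its own gold first; recovered category
counts then track injected rates to within binomial noise (plus a small,
quantified deduplication effect when two boundary variants collapse to the
same string). Note the bookkeeping consequence tests must respect: a
type-confused mention is also absent from its own task's output, so
expected misses pool p_miss + p_type.

The mock embedder hashes character 3-grams into ±1 contributions and
L2-normalizes, so identical texts coincide and texts sharing n-grams are
nearer than token-disjoint texts. It captures *surface* similarity only —
none of the semantics a learned embedding would add — so selection tests
demonstrate the machinery's correctness, not retrieval quality on real
clinical text.

What passing tests therefore show: the harness computes its statistics
exactly as specified and recovers known ground truth under its own noise
model. What they do not show: anything about a real LLM's behavior, real
annotation noise, or real embedding geometry.

## Problem sizes

The test suite and acceptance script size their simulations for fast,
deterministic execution while keeping statistical checks meaningful:
identity and corrupted runs use 208-document corpora (the real test-split
size), rate-recovery uses 1,000 documents (~13,000 mentions, giving 3σ
binomial bands of roughly ±1 percentage point), bootstrap checks use 2,000
replicates, and enumeration-based oracles run on 3 documents where the
exact distribution (27 resamples) is computable.
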