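"""Synthetic corpora, deterministic mock embeddings, and corruption channels.

No public accession exists for the annotated rare-disease report corpus the
framework targets, so every stage is exercised against synthetic data that
emulates its *structure*: plain-text documents carrying annotated surface
mentions of four entity types with a strongly imbalanced, long-tailed type
distribution (defaults reproduce the real corpus's scale: 1,041 documents
and per-document mention means of roughly 5.0 / 2.3 / 5.1 / 0.4 for rare
disease / disease / sign / symptom).  The generator makes no attempt at
linguistic realism — documents are filler tokens with mention surfaces
spliced in — which is exactly what makes its bookkeeping exact.

The corruption channel turns gold labels into model-output strings with
controllable, mention-level i.i.d. error rates per failure mode (boundary
drift, type confusion, misses, spurious emissions, including spurious
symptom outputs copied from gold signs), so downstream metrics and the
error taxonomy have analytically known ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus import (
    AnnotatedCorpus,
    AnnotatedDocument,
    EntityMention,
    EntityType,
)

__all__ = [
    "CorpusSpec",
    "CorruptionSpec",
    "generate_corpus",
    "corrupt_outputs",
    "mock_embed",
    "default_vocabulary",
]

# Disjoint per-type vocabularies of multi-token surface forms.  Disjointness
# (including at token level across types) keeps corruption ground truth
# unambiguous: a type-confused emission can only align to its own gold.
_ADJ = {
    EntityType.RARE_DISEASE: ["myelic", "kranon", "velgar", "ostrine", "dulmar",
                              "ferrun", "galpin", "harvel", "ixodal", "jorvik"],
    EntityType.DISEASE: ["common", "chronic", "acute", "viral", "systemic",
                         "regional", "seasonal", "latent", "benign", "focal"],
    EntityType.SIGN: ["elevated", "reduced", "enlarged", "irregular", "persistent",
                      "abnormal", "diffuse", "localized", "marked", "mild"],
    EntityType.SYMPTOM: ["burning", "throbbing", "intermittent", "sharp", "dull",
                         "radiating", "constant", "episodic", "nocturnal", "morning"],
}
_NOUN = {
    EntityType.RARE_DISEASE: ["syndrome", "dystrophy", "anomaly", "disorder",
                              "deficiency", "atrophy", "agenesis", "dysplasia",
                              "sclerosis", "aplasia"],
    EntityType.DISEASE: ["infection", "inflammation", "hypertension", "anemia",
                         "dermatitis", "arthritis", "neuropathy", "colitis",
                         "nephritis", "myopathy"],
    EntityType.SIGN: ["rash", "swelling", "murmur", "lesion", "bruising", "pallor",
                      "edema", "cyanosis", "nystagmus", "clubbing"],
    EntityType.SYMPTOM: ["ache", "nausea", "dizziness", "tingling", "itching",
                         "soreness", "cramping", "stiffness", "malaise", "heaviness"],
}
_FILLER = (
    "the patient report describes findings observed during examination and "
    "follow up with additional notes on history course management and outcome "
    "recorded by the clinical team over several visits"
).split()
_NOISE_TOKENS = ["zorbel", "quanth", "fimbra", "oxtal", "wrenit", "plome",
                 "drathe", "kelvix", "sunder", "yarrol"]


def default_vocabulary(etype: EntityType) -> list[str]:
    """All two-token surface forms for one entity type (100 per type)."""
    etype = EntityType(etype)
    return [f"{a} {n}" for a in _ADJ[etype] for n in _NOUN[etype]]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the synthetic corpus generator.

    ``mention_rates`` are per-document Poisson means per entity type; the
    defaults reproduce the real corpus's per-type totals divided by its
    1,041 documents (symptom sparsity included).
    """

    n_docs: int = 1041
    mention_rates: Mapping[EntityType, float] = field(
        default_factory=lambda: {
            EntityType.RARE_DISEASE: 5.0,
            EntityType.DISEASE: 2.3,
            EntityType.SIGN: 5.1,
            EntityType.SYMPTOM: 0.4,
        }
    )
    doc_length_range: tuple[int, int] = (60, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.mention_rates.values()):
            raise ValueError("mention rates must be non-negative")


def generate_corpus(spec: CorpusSpec) -> tuple[AnnotatedCorpus, dict]:
    """Generate a corpus plus exact generator bookkeeping.

    Per document and type, a Poisson-distributed number of surfaces is drawn
    *without replacement* from that type's vocabulary (so each document's
    per-type gold set size equals its mention count) and spliced verbatim
    into a filler-token document.  Returns ``(corpus, bookkeeping)`` where
    bookkeeping maps each type to its true total mention count.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = {e: default_vocabulary(e) for e in EntityType}
    for e, rate in spec.mention_rates.items():
        if rate > 0 and not vocab[EntityType(e)]:
            raise ValueError(f"vocabulary for {e} is empty")
    docs: list[AnnotatedDocument] = []
    true_counts = {e: 0 for e in EntityType}
    lo, hi = spec.doc_length_range
    for i in range(spec.n_docs):
        n_filler = int(rng.integers(lo, hi + 1))
        words = [str(_FILLER[int(j)]) for j in rng.integers(0, len(_FILLER), n_filler)]
        mentions_spec: list[tuple[str, EntityType]] = []
        for etype in EntityType:
            rate = spec.mention_rates.get(etype, 0.0)
            if rate == 0:
                continue
            n_m = int(rng.poisson(rate))
            n_m = min(n_m, len(vocab[etype]))  # vocab is ample for default rates
            if n_m == 0:
                continue
            chosen = rng.choice(len(vocab[etype]), size=n_m, replace=False)
            mentions_spec.extend((vocab[etype][int(c)], etype) for c in chosen)
        # splice each mention at a random word boundary
        positions = sorted(
            (int(p) for p in rng.integers(0, len(words) + 1, len(mentions_spec))),
            reverse=True,
        )
        order = rng.permutation(len(mentions_spec))
        for pos, mi in zip(positions, order):
            words.insert(pos, mentions_spec[int(mi)][0])
        text = " ".join(words)
        mentions: list[EntityMention] = []
        cursor: dict[str, int] = {}
        for surface, etype in mentions_spec:
            start = text.index(surface, cursor.get(surface, 0))
            cursor[surface] = start + 1
            mentions.append(
                EntityMention(surface=surface, etype=etype,
                              char_start=start, char_end=start + len(surface))
            )
            true_counts[etype] += 1
        docs.append(AnnotatedDocument(doc_id=f"syn{i:05d}", text=text, mentions=mentions))
    return AnnotatedCorpus(docs), {"true_counts": true_counts, "seed": spec.seed}


@dataclass(frozen=True)
class CorruptionSpec:
    """Mention-level i.i.d. error channel over gold labels.

    Per gold mention: with ``p_miss`` it is omitted; with ``p_boundary`` it is
    emitted with a token dropped (or an extra token when single-token); with
    ``p_type`` it is emitted under a different entity-type task; otherwise it
    is emitted verbatim.  Independently, each (document, task) output gains
    Poisson(``spurious_rate``) spurious strings; for the symptom task a
    fraction ``sign_copy_fraction`` of them are copies of same-document gold
    sign mentions (emulating sign/symptom boundary confusion), the rest are
    noise strings sharing no tokens with any gold.
    """

    p_boundary: float = 0.0
    p_type: float = 0.0
    p_miss: float = 0.0
    spurious_rate: float = 0.0
    sign_copy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_boundary", "p_type", "p_miss", "sign_copy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_boundary + self.p_type + self.p_miss > 1.0 + 1e-12:
            raise ValueError("p_boundary + p_type + p_miss must not exceed 1")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")


def _boundary_variant(surface: str, rng: np.random.Generator) -> str:
    toks = surface.split()
    if len(toks) > 1:
        drop = int(rng.integers(0, len(toks)))
        toks = toks[:drop] + toks[drop + 1 :]
        return " ".join(toks)
    return surface + " " + _NOISE_TOKENS[int(rng.integers(0, len(_NOISE_TOKENS)))]


def corrupt_outputs(
    corpus: AnnotatedCorpus, spec: CorruptionSpec
) -> tuple[dict[tuple[str, str], str], dict]:
    """Apply the corruption channel to every (document, entity type) query.

    Returns ``(outputs, manifest)``: ``outputs`` maps
    ``(doc_id, etype_value)`` to the raw comma-joined answer string (the
    literal ``"none"`` when empty), and ``manifest`` records the injected
    per-mode counts so tests can recover them.  With all rates zero the
    outputs equal the flattened gold labels exactly.
    """
    rng = np.random.default_rng(spec.seed)
    # exact-string emissions are placed before boundary-corrupted ones in the
    # output order so greedy alignment lets each exact emission claim its own
    # gold first; spurious strings come last.
    exact: dict[tuple[str, str], list[str]] = {
        (d.doc_id, e.value): [] for d in corpus for e in EntityType
    }
    fuzzy = {k: [] for k in exact}
    noise = {k: [] for k in exact}
    injected = {c: 0 for c in ("correct", "boundary", "type", "miss", "spurious",
                               "spurious_sign_copy")}
    etypes = list(EntityType)
    for doc in corpus:
        for m in doc.mentions:
            u = rng.random()
            if u < spec.p_miss:
                injected["miss"] += 1
                continue
            if u < spec.p_miss + spec.p_boundary:
                fuzzy[(doc.doc_id, m.etype.value)].append(
                    _boundary_variant(m.surface, rng)
                )
                injected["boundary"] += 1
            elif u < spec.p_miss + spec.p_boundary + spec.p_type:
                others = [e for e in etypes if e != m.etype]
                target = others[int(rng.integers(0, len(others)))]
                exact[(doc.doc_id, target.value)].append(m.surface)
                injected["type"] += 1
            else:
                exact[(doc.doc_id, m.etype.value)].append(m.surface)
                injected["correct"] += 1
        if spec.spurious_rate > 0:
            for etype in etypes:
                n_sp = int(rng.poisson(spec.spurious_rate))
                sign_surfaces = [x.surface for x in doc.mentions_of(EntityType.SIGN)]
                for _ in range(n_sp):
                    copy_sign = (
                        etype is EntityType.SYMPTOM
                        and rng.random() < spec.sign_copy_fraction
                    )
                    if copy_sign:
                        if not sign_surfaces:
                            continue  # no sign to copy: emit nothing, keep truth exact
                        s = sign_surfaces[int(rng.integers(0, len(sign_surfaces)))]
                        injected["spurious_sign_copy"] += 1
                    else:
                        a, b = rng.integers(0, len(_NOISE_TOKENS), 2)
                        s = f"{_NOISE_TOKENS[int(a)]} {_NOISE_TOKENS[int(b)]}"
                    noise[(doc.doc_id, etype.value)].append(s)
                    injected["spurious"] += 1
    raw = {}
    for key in exact:
        vals = exact[key] + fuzzy[key] + noise[key]
        raw[key] = ", ".join(vals) if vals else "none"
    manifest = {"injected": injected, "spec": spec}
    return raw, manifest


def mock_embed(text: str, d: int = 3072, seed: int = 0) -> np.ndarray:
    """Deterministic text embedding from hashed character 3-grams.

    Each 3-gram of the lowercased text contributes +/-1 at a hash-derived
    coordinate; the sum is L2-normalized.  Identical texts map to identical
    vectors, and texts sharing many n-grams land nearer (Euclidean) than
    texts with disjoint vocabulary — enough structure for exercising
    similarity-based selection without a learned model.
    """
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    vec = np.zeros(d)
    s = text.lower()
    grams = [s[i : i + 3] for i in range(max(len(s) - 2, 1))]
    for g in grams:
        h = hashlib.blake2b(f"{seed}|{g}".encode("utf-8"), digest_size=8).digest()
        val = int.from_bytes(h, "big")
        vec[val % d] += 1.0 if (val >> 63) & 1 else -1.0
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec
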