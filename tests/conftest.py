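import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from promptner.corpus import (
    AnnotatedCorpus,
    AnnotatedDocument,
    EntityMention,
    EntityType,
)


@pytest.fixture
def tiny_doc() -> AnnotatedDocument:
    text = (
        "Myhre syndrome is rare. Patients show orthostatic hypotension and "
        "report fatigue daily."
    )
    return AnnotatedDocument(
        doc_id="d1",
        text=text,
        mentions=[
            EntityMention("Myhre syndrome", EntityType.RARE_DISEASE, 0, 14),
            EntityMention("orthostatic hypotension", EntityType.SIGN, 38, 61),
            EntityMention("fatigue", EntityType.SYMPTOM, 73, 80),
        ],
    )


@pytest.fixture
def tiny_corpus(tiny_doc) -> AnnotatedCorpus:
    d2 = AnnotatedDocument(
        doc_id="d2",
        text="May-Hegglin Anomaly is a blood platelet disorder, a blood platelet disorder.",
        mentions=[
            EntityMention("May-Hegglin Anomaly", EntityType.RARE_DISEASE),
            EntityMention("blood platelet disorder", EntityType.DISEASE),
            EntityMention("blood platelet disorder", EntityType.DISEASE),
        ],
    )
    d3 = AnnotatedDocument(doc_id="d3", text="No findings reported.", mentions=[])
    return AnnotatedCorpus([tiny_doc, d2, d3])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
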