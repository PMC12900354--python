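"""Generation contract, deterministic mock backends, fine-tune export.

Actual hosted-model inference and gradient fine-tuning are external
services; this module defines the contract they must satisfy and ships
deterministic mock backends so the whole experiment pipeline is testable
offline:

* ``ScriptedBackend`` — answers keyed by (doc_id, entity type); records every
  prompt it receives for test assertions.
* ``EchoGoldBackend`` — returns the flattened gold labels (the identity
  channel: downstream evaluation must score exactly 1.0 on it).
* ``CorruptionBackend`` — wraps a pre-computed corruption of gold labels
  (see :mod:`promptner.synthetic`), emulating the known failure modes.

Fine-tuning itself is a hosted-service action; the module exports its JSONL
input format (chat-message or prompt/completion layout) and stops there.
"""

from __future__ import annotations

import json
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

from .corpus import AnnotatedCorpus, AnnotatedDocument, EntityType, Split, flatten_labels
from .cost_model import WHITESPACE_TOKENIZER_ID, count_tokens
from .prompting import AssembledPrompt, PromptComponentSet, assemble_prompt

__all__ = [
    "GenerationRequest",
    "GenerationResult",
    "Backend",
    "ScriptedBackend",
    "EchoGoldBackend",
    "CorruptionBackend",
    "OpenAICompatibleBackend",
    "generate",
    "export_finetune_jsonl",
]


@dataclass(frozen=True)
class GenerationRequest:
    prompt: AssembledPrompt
    model_id: str = "mock"
    doc_id: str | None = None
    etype: EntityType | None = None
    temperature: float = 0.0
    max_output_tokens: int = 256

    def __post_init__(self) -> None:
        if not self.prompt.full_text:
            raise ValueError("prompt must be non-empty")


@dataclass(frozen=True)
class GenerationResult:
    raw_text: str
    input_token_count: int
    backend_id: str

    def __post_init__(self) -> None:
        if self.input_token_count < 1:
            raise ValueError("input_token_count must be >= 1")


class Backend(Protocol):
    backend_id: str

    def complete(self, request: GenerationRequest) -> str:  # pragma: no cover
        ...


@dataclass
class ScriptedBackend:
    """Deterministic mock answering from a (doc_id, etype) -> text script."""

    scripts: Mapping[tuple[str, str], str]
    backend_id: str = "scripted-mock"
    received_prompts: list[GenerationRequest] = field(default_factory=list)

    def complete(self, request: GenerationRequest) -> str:
        self.received_prompts.append(request)
        key = (request.doc_id, request.etype.value if request.etype else None)
        if key not in self.scripts:
            raise KeyError(f"scripted mock has no answer for {key}")
        return self.scripts[key]


@dataclass
class EchoGoldBackend:
    """Identity channel: returns the flattened gold labels for the query."""

    corpus: AnnotatedCorpus
    backend_id: str = "echo-gold-mock"

    def __post_init__(self) -> None:
        self._by_id = {d.doc_id: d for d in self.corpus}

    def complete(self, request: GenerationRequest) -> str:
        if request.doc_id is None or request.etype is None:
            raise ValueError("echo-gold backend needs doc_id and etype on the request")
        return flatten_labels(self._by_id[request.doc_id], request.etype)


@dataclass
class CorruptionBackend:
    """Serves pre-computed corrupted outputs keyed by (doc_id, etype)."""

    outputs: Mapping[tuple[str, str], str]
    backend_id: str = "corruption-mock"

    def complete(self, request: GenerationRequest) -> str:
        key = (request.doc_id, request.etype.value if request.etype else None)
        if key not in self.outputs:
            raise KeyError(f"corruption mock has no output for {key}")
        return self.outputs[key]


@dataclass
class OpenAICompatibleBackend:
    """Thin HTTP adapter for an OpenAI-style chat-completions endpoint.

    Optional convenience for live runs; experiments and tests use the mock
    backends.  Retries transient failures 3 times with exponential backoff.
    """

    api_url: str
    api_key: str
    model_id: str
    backend_id: str = "openai-compatible"
    max_retries: int = 3

    def complete(self, request: GenerationRequest) -> str:  # pragma: no cover - network
        payload = json.dumps(
            {
                "model": self.model_id,
                "temperature": request.temperature,
                "max_tokens": request.max_output_tokens,
                "messages": [{"role": "user", "content": request.prompt.full_text}],
            }
        ).encode("utf-8")
        last_exc: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                req = urllib.request.Request(
                    self.api_url,
                    data=payload,
                    headers={
                        "Content-Type": "application/json",
                        "Authorization": f"Bearer {self.api_key}",
                    },
                )
                with urllib.request.urlopen(req, timeout=60) as resp:
                    body = json.loads(resp.read().decode("utf-8"))
                return body["choices"][0]["message"]["content"]
            except Exception as exc:  # noqa: BLE001 - retried then re-raised
                last_exc = exc
                time.sleep(2.0**attempt)
        raise RuntimeError(
            f"backend failed after {self.max_retries} attempts: {last_exc}"
        ) from last_exc


def generate(request: GenerationRequest, backend: Backend) -> GenerationResult:
    """Run one generation through the configured backend.

    The input token count is computed locally (whitespace tokenizer contract)
    so cost accounting does not depend on backend-reported usage.
    """
    raw = backend.complete(request)
    return GenerationResult(
        raw_text=raw,
        input_token_count=max(1, count_tokens(request.prompt.full_text)),
        backend_id=backend.backend_id,
    )


def export_finetune_jsonl(
    docs: Sequence[AnnotatedDocument],
    components_by_etype: Mapping[EntityType, PromptComponentSet],
    path: str | Path,
    layout: str = "chat",
) -> int:
    """Export fine-tuning records: one per (document, entity type).

    Each record pairs the fully assembled prompt (basic + advanced
    components + the document text) with the flattened gold labels as the
    completion.  ``layout`` selects the chat-message schema (default) or the
    legacy prompt/completion schema.  Re-export is byte-identical.
    """
    if layout not in {"chat", "completion"}:
        raise ValueError(f"unknown layout {layout!r}")
    for doc in docs:
        if doc.split not in {Split.TRAIN, Split.VAL}:
            raise ValueError(
                f"document {doc.doc_id!r} is not in the train or val split"
            )
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            for etype, components in components_by_etype.items():
                prompt = assemble_prompt(components, doc.text)
                completion = flatten_labels(doc, etype)
                if layout == "chat":
                    rec = {
                        "messages": [
                            {"role": "user", "content": prompt.full_text},
                            {"role": "assistant", "content": completion},
                        ]
                    }
                else:
                    rec = {"prompt": prompt.full_text, "completion": completion}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
                n += 1
    return n
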