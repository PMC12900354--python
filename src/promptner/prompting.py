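"""Structured prompt assembly.

A prompt is the ordered concatenation of up to seven segments:

    task description || output format || task guidance || disambiguation rule
        || exemplars || knowledge snippets || inquiry

The first two (plus the inquiry prefix) are the *basic* components; guidance
and disambiguation are the *advanced* components; exemplars and snippets are
the few-shot and retrieval-augmented additions.  Assembly is a pure function:
identical inputs yield byte-identical prompt text, so token counts and costs
are reproducible.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import yaml

from .corpus import EntityType

if TYPE_CHECKING:  # pragma: no cover
    from .selection import ExemplarSet

__all__ = [
    "PromptComponentSet",
    "AssembledPrompt",
    "load_default_components",
    "assemble_prompt",
    "render_exemplar",
    "EXEMPLAR_PREFIX",
    "SNIPPET_PREFIX",
    "SEGMENT_SEPARATOR",
]

#: Prefix line opening the in-context exemplar block.
EXEMPLAR_PREFIX = "Here are demonstration shots:"
#: Prefix line opening the retrieved-knowledge block.
SNIPPET_PREFIX = "Here are knowledge snippets:"
#: Canonical inter-segment separator (one blank line).
SEGMENT_SEPARATOR = "\n\n"


@dataclass(frozen=True)
class PromptComponentSet:
    """Per-entity-type prompt component texts.

    ``task_guidance`` and ``disambiguation_rule`` are present iff the
    configuration enables the advanced components.
    """

    etype: EntityType
    task_description: str
    output_format: str
    input_prefix: str
    task_guidance: str | None = None
    disambiguation_rule: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "etype", EntityType(self.etype))
        for name in ("task_description", "output_format", "input_prefix"):
            if not getattr(self, name).strip():
                raise ValueError(f"{name} must be non-empty")

    def basic_only(self) -> "PromptComponentSet":
        """A copy with the advanced components removed."""
        return PromptComponentSet(
            etype=self.etype,
            task_description=self.task_description,
            output_format=self.output_format,
            input_prefix=self.input_prefix,
        )


@dataclass(frozen=True)
class AssembledPrompt:
    """Ordered prompt segments plus their joined text."""

    segments: tuple[tuple[str, str], ...]  # (segment_kind, text)
    full_text: str
    token_count: int | None = None

    @property
    def segment_kinds(self) -> tuple[str, ...]:
        return tuple(kind for kind, _ in self.segments)

    def with_token_count(self, count: int) -> "AssembledPrompt":
        return AssembledPrompt(self.segments, self.full_text, token_count=count)


def load_default_components(
    etype: EntityType, advanced: bool = True
) -> PromptComponentSet:
    """Load the shipped per-entity component texts.

    ``advanced=False`` returns the basic-only set (no guidance, no
    disambiguation rule).
    """
    etype = EntityType(etype)
    ref = importlib.resources.files("promptner.templates") / "components.yaml"
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))[etype.value]
    comp = PromptComponentSet(
        etype=etype,
        task_description=data["task_description"],
        output_format=data["output_format"],
        input_prefix=data["input_prefix"],
        task_guidance=data["task_guidance"] if advanced else None,
        disambiguation_rule=data["disambiguation_rule"] if advanced else None,
    )
    return comp


def render_exemplar(input_text: str, label: str) -> str:
    """Render one demonstration pair as an ``Input text: ... Output: ...`` block."""
    return f"Input text: {input_text}\nOutput: {label}."


def assemble_prompt(
    components: PromptComponentSet,
    inquiry: str,
    exemplars: "ExemplarSet | None" = None,
    snippets: Sequence[str] | None = None,
    separator: str = SEGMENT_SEPARATOR,
) -> AssembledPrompt:
    """Assemble the full prompt for one inquiry.

    Segment order is basic || advanced || exemplars || snippets || inquiry;
    in the combined few-shot + retrieval mode the exemplar block precedes the
    snippet block.  Omitting ``exemplars`` and ``snippets`` yields the
    zero-shot prompt.  Passing an explicitly empty exemplar set or snippet
    list is an error: zero-shot must be expressed by omission so that mode
    bookkeeping stays unambiguous.
    """
    if not inquiry.strip():
        raise ValueError("inquiry must be non-empty")
    if exemplars is not None and exemplars.k == 0:
        raise ValueError("empty ExemplarSet passed; omit the argument for zero-shot")
    if snippets is not None and len(snippets) == 0:
        raise ValueError("empty snippet list passed; omit the argument instead")

    segments: list[tuple[str, str]] = [
        ("task_description", components.task_description),
        ("output_format", components.output_format),
    ]
    if components.task_guidance is not None:
        segments.append(("task_guidance", components.task_guidance))
    if components.disambiguation_rule is not None:
        segments.append(("disambiguation_rule", components.disambiguation_rule))
    if exemplars is not None:
        blocks = [render_exemplar(x, y) for x, y in exemplars.pairs]
        segments.append(("exemplars", "\n".join([EXEMPLAR_PREFIX, *blocks])))
    if snippets is not None:
        segments.append(("snippets", "\n".join([SNIPPET_PREFIX, *snippets])))
    segments.append(("inquiry", f"{components.input_prefix} {inquiry}"))

    full_text = separator.join(text for _, text in segments)
    return AssembledPrompt(segments=tuple(segments), full_text=full_text)
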