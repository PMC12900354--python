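"""Assemble zero-shot, few-shot, and retrieval-augmented prompts.

A prompt is the ordered concatenation of task description, output format,
optional guidance and disambiguation rule, optional exemplar and snippet
blocks, and the inquiry text.  Assembly is byte-reproducible, so token
counts (and therefore costs) are too.
"""

from promptner import (
    EntityType,
    assemble_prompt,
    count_tokens,
    load_default_components,
)
from promptner.selection import ExemplarSet, SelectionMethod

components = load_default_components(EntityType.RARE_DISEASE)
inquiry = ("Myhre syndrome is an extremely rare inherited disorder affecting "
           "males and females in equal numbers.")

zero_shot = assemble_prompt(components, inquiry)
exemplars = ExemplarSet(
    pairs=(("Kranon dystrophy presents in infancy.", "kranon dystrophy"),),
    method=SelectionMethod.INQUIRY_KNN,
    doc_ids=("train-042",),
)
few_shot = assemble_prompt(components, inquiry, exemplars=exemplars)
rag = assemble_prompt(components, inquiry, exemplars=exemplars,
                      snippets=["myhre syndrome: a rare connective tissue disorder"])

for name, prompt in [("zero-shot", zero_shot), ("one-shot", few_shot),
                     ("one-shot + 1 snippet", rag)]:
    print(f"{name}: segments {list(prompt.segment_kinds)}, "
          f"{count_tokens(prompt.full_text)} tokens")
print()
print(rag.full_text)
# Segment kinds show the composition order (exemplars before snippets in the
# combined mode); the token counts drive the per-query cost model.
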