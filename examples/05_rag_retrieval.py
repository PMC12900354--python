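"""Index a small knowledge corpus and retrieve the nearest snippets.

Each (disease name, definition) entry is embedded once; retrieval returns
the K entries nearest to the inquiry embedding, which are injected into the
prompt under the knowledge-snippet prefix.
"""

from promptner import build_index, mock_embed, retrieve_topk
from promptner.rag import format_snippet

entries = [
    ("myhre syndrome", "a rare connective tissue disorder with short stature "
                       "and thickened skin"),
    ("kranon dystrophy", "a progressive muscle-wasting disorder of infancy"),
    ("velgar anomaly", "a congenital malformation of the great vessels"),
    ("common cold", "a mild viral infection of the upper respiratory tract"),
]
embedder = lambda text: mock_embed(text, d=256, seed=4)
index = build_index(entries, embedder)
print(f"indexed T={index.t} entries, median snippet length "
      f"{index.median_token_length:.0f} tokens")

inquiry = ("An infant presenting with progressive muscle wasting and delayed "
           "milestones was evaluated for a hereditary disorder.")
for entry in retrieve_topk(embedder(inquiry), index, 2):
    print(" ", format_snippet(entry))
# The muscle-wasting definition ranks first because retrieval is nearest-
# neighbour in embedding space; the retrieved lines are exactly what the
# prompt assembler places under "Here are knowledge snippets:".
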