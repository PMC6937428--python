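"""Explain a predicted treatment link by its best literature paths.

Reproduces the published worked example: all simple paths of four or fewer
nodes between acetazolamide (ACZ) and amyotrophic lateral sclerosis (ALS)
are enumerated, each edge is reduced to its highest-supported theme, and
paths are ranked by their minimum support (weakest link).
"""

from ukge.kg import EntityType, KnowledgeGraph, WeightedTriple
from ukge.paths import explain_prediction, potential_mediators

graph = KnowledgeGraph(
    entities={
        "acetazolamide": EntityType.DRUG,
        "glaucoma": EntityType.DISEASE,
        "OPTN": EntityType.GENE,
        "ALS": EntityType.DISEASE,
    },
    triples=[
        WeightedTriple("acetazolamide", "T", "glaucoma", 0.937),
        WeightedTriple("glaucoma", "U", "OPTN", 0.904),
        WeightedTriple("ALS", "U", "OPTN", 0.906),
    ],
)

for exp in explain_prediction(graph, "acetazolamide", "ALS", top_k=10):
    chain = " - ".join(
        f"({n}) [{c} {s:.3f}]" for n, (c, s) in zip(exp.nodes, exp.edges)
    ) + f" - ({exp.nodes[-1]})"
    print(f"score={exp.score:.3f} motif={exp.motif}: {chain}")

meds = potential_mediators(
    explain_prediction(graph, "acetazolamide", "ALS", top_k=10), graph.entities
)
print(f"potential mediators (interior genes of top paths): {meds}")
print("reading: ACZ treats glaucoma, which shares a causal OPTN mutation "
      "with ALS — a mechanistic link, but not evidence that ACZ targets OPTN")
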