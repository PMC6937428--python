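"""Explanation mining: rank short drug-disease paths by literature support.

A prediction (drug, treats, disease) is explained by enumerating all simple
undirected paths of up to four nodes between the two entities, reducing
every edge to its highest-supported theme, and scoring each path by the
minimum of those supports — a weakest-link measure of how well the whole
chain of assertions is backed by literature.  Four-node paths fall into
type-level metapath motifs: drug-disease-gene-disease (DzG-mediated),
drug-disease-drug-disease (DzDr-mediated) and drug-gene-gene-disease
(GG-mediated).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .kg import EntityType, KnowledgeGraph

MOTIFS = ("DzG", "DzDr", "GG", "direct", "other")


class PathEnumerationOverflow(RuntimeError):
    """Raised when a pair has more candidate paths than the configured cap."""


@dataclass(frozen=True)
class ExplanationPath:
    """A simple path with per-edge best theme/support and min-support score."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, float], ...]   # (best theme code, best support) per step
    score: float
    motif: str


def enumerate_paths(
    graph: KnowledgeGraph | nx.Graph,
    source: str,
    target: str,
    max_nodes: int = 4,
    cap: int = 10**6,
) -> set[tuple[str, ...]]:
    """All simple undirected paths from source to target with between 2 and
    ``max_nodes`` nodes inclusive (i.e. up to max_nodes - 1 edges)."""
    g = graph.to_networkx() if isinstance(graph, KnowledgeGraph) else graph
    for node in (source, target):
        if node not in g:
            raise KeyError(f"node {node!r} not in graph")
    if source == target:
        raise ValueError("source and target must differ")
    out: set[tuple[str, ...]] = set()
    for path in nx.all_simple_paths(g, source, target, cutoff=max_nodes - 1):
        out.add(tuple(path))
        if len(out) > cap:
            raise PathEnumerationOverflow(
                f"more than {cap} paths between {source!r} and {target!r}"
            )
    return out


def best_theme(graph: KnowledgeGraph | nx.Graph, u: str, v: str) -> tuple[str, float]:
    """The highest-supported theme over all triples linking u and v in either
    orientation; ties broken alphabetically by code."""
    g = graph.to_networkx() if isinstance(graph, KnowledgeGraph) else graph
    if not g.has_edge(u, v):
        raise KeyError(f"no edge between {u!r} and {v!r}")
    triples = g[u][v]["triples"]
    winner = min(triples, key=lambda t: (-t.support, t.theme))
    return winner.theme, winner.support


def classify_motif(
    nodes: tuple[str, ...] | list[str],
    types: dict[str, EntityType],
) -> str:
    """Metapath motif of a path whose endpoints are a drug and a disease.

    Four-node paths map to DzG / DzDr / GG by their interior node types
    (after orienting the path drug-to-disease); two-node paths are
    ``direct``; everything else is ``other``.
    """
    nodes = tuple(nodes)
    end_types = (types[nodes[0]], types[nodes[-1]])
    if set(end_types) != {EntityType.DRUG, EntityType.DISEASE}:
        raise ValueError(
            f"path endpoints must be a drug and a disease, got "
            f"({end_types[0].value}, {end_types[1].value})"
        )
    if end_types[0] == EntityType.DISEASE:
        nodes = nodes[::-1]
    if len(nodes) == 2:
        return "direct"
    if len(nodes) == 4:
        interior = (types[nodes[1]], types[nodes[2]])
        if interior == (EntityType.DISEASE, EntityType.GENE):
            return "DzG"
        if interior == (EntityType.DISEASE, EntityType.DRUG):
            return "DzDr"
        if interior == (EntityType.GENE, EntityType.GENE):
            return "GG"
    return "other"


def score_path(
    path: tuple[str, ...] | list[str],
    graph: KnowledgeGraph | nx.Graph,
    types: dict[str, EntityType] | None = None,
) -> ExplanationPath:
    """Reduce each step to its best theme and score the path by the minimum
    support along it."""
    nodes = tuple(path)
    if len(nodes) < 2:
        raise ValueError("a path needs at least two nodes")
    if types is None and isinstance(graph, KnowledgeGraph):
        types = graph.entities
    g = graph.to_networkx() if isinstance(graph, KnowledgeGraph) else graph
    edges = tuple(best_theme(g, u, v) for u, v in zip(nodes, nodes[1:]))
    score = min(s for _, s in edges)
    motif = "other"
    if types is not None:
        try:
            motif = classify_motif(nodes, types)
        except ValueError:
            motif = "other"
    return ExplanationPath(nodes=nodes, edges=edges, score=score, motif=motif)


def explain_prediction(
    graph: KnowledgeGraph,
    drug: str,
    disease: str,
    top_k: int = 100,
    max_nodes: int = 4,
    cap: int = 10**6,
) -> list[ExplanationPath]:
    """Top-k ranked explanation paths between a drug and a disease.

    Paths are sorted by descending min-support score; ties go to shorter
    paths first, then lexicographic node sequence.  Returns an empty list
    when no path exists.
    """
    g = graph.to_networkx()
    paths = enumerate_paths(g, drug, disease, max_nodes=max_nodes, cap=cap)
    scored = [score_path(p, g, types=graph.entities) for p in paths]
    scored.sort(key=lambda e: (-e.score, len(e.nodes), e.nodes))
    return scored[:top_k]


def potential_mediators(explanations: list[ExplanationPath],
                        types: dict[str, EntityType]) -> list[str]:
    """Interior gene nodes of the ranked paths, in order of first appearance."""
    seen: dict[str, None] = {}
    for exp in explanations:
        for node in exp.nodes[1:-1]:
            if types.get(node) == EntityType.GENE:
                seen.setdefault(node)
    return list(seen)


@dataclass
class MotifDistribution:
    """Motif occurrence counts per assessment category over each pair's
    top-k explanation paths (direct edges excluded)."""

    counts: "pd.DataFrame"   # index: category, columns: motifs
    top_k: int


def motif_distribution(
    explanations: dict[tuple[str, str], list[ExplanationPath]],
    categories: dict[tuple[str, str], str],
    top_k: int = 100,
) -> MotifDistribution:
    import pandas as pd

    motif_cols = [m for m in MOTIFS if m != "direct"]
    labels = sorted(set(categories.values()))
    counts = pd.DataFrame(0, index=labels, columns=motif_cols, dtype=int)
    for pair, paths in explanations.items():
        label = categories.get(pair)
        if label is None:
            continue
        for exp in paths[:top_k]:
            if exp.motif == "direct":
                continue
            counts.loc[label, exp.motif] += 1
    return MotifDistribution(counts=counts, top_k=top_k)
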