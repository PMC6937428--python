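"""Data model, file I/O, filtering, submodels and splits for support-scored
heterogeneous knowledge graphs.

A graph holds typed entities (drug / disease / gene) and themed multi-edges,
each carrying a literature support score in [0, 1].  Connectivity is always
treated as undirected and theme-agnostic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np


class GraphParseError(ValueError):
    """Raised when a graph file contains a malformed row."""


class EntityType(str, enum.Enum):
    DRUG = "drug"
    DISEASE = "disease"
    GENE = "gene"


#: Unordered entity-type pair admitted by each theme category.
CATEGORY_TYPE_PAIRS: dict[str, frozenset[EntityType]] = {
    "Dr-Dz": frozenset({EntityType.DRUG, EntityType.DISEASE}),
    "Dr-G": frozenset({EntityType.DRUG, EntityType.GENE}),
    "Dz-G": frozenset({EntityType.DISEASE, EntityType.GENE}),
    "G-G": frozenset({EntityType.GENE}),
}


@dataclass(frozen=True)
class Theme:
    """A semantic relationship label within one entity-pair category."""

    code: str
    category: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_TYPE_PAIRS:
            raise ValueError(f"unknown theme category {self.category!r}")


@dataclass(frozen=True, order=True)
class WeightedTriple:
    """One (head, theme, tail) assertion with literature support in [0, 1]."""

    head: str
    theme: str
    tail: str
    support: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.support <= 1.0) or not math.isfinite(self.support):
            raise ValueError(
                f"support {self.support!r} outside [0, 1] for ({self.head}, "
                f"{self.theme}, {self.tail})"
            )
        if self.head == self.tail:
            raise ValueError(f"self-loop on entity {self.head!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.head, self.tail))


@dataclass
class KnowledgeGraph:
    """Typed entities plus themed, support-scored multi-edges."""

    entities: dict[str, EntityType]
    triples: list[WeightedTriple]
    vocabulary: list[Theme] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        codes_by_pair: dict[frozenset[EntityType], set[str]] = {}
        for theme in self.vocabulary:
            codes_by_pair.setdefault(CATEGORY_TYPE_PAIRS[theme.category], set()).add(
                theme.code
            )
        for t in self.triples:
            for endpoint in (t.head, t.tail):
                if endpoint not in self.entities:
                    raise ValueError(f"triple endpoint {endpoint!r} not in entities")
            if self.vocabulary:
                pair = frozenset(
                    {self.entities[t.head], self.entities[t.tail]}
                )
                if t.theme not in codes_by_pair.get(pair, set()):
                    raise ValueError(
                        f"theme {t.theme!r} incompatible with entity types "
                        f"({self.entities[t.head].value}, {self.entities[t.tail].value})"
                    )

    # -- views --------------------------------------------------------------

    @property
    def theme_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for theme in self.vocabulary:
            seen.setdefault(theme.code)
        for t in self.triples:
            seen.setdefault(t.theme)
        return list(seen)

    def entities_of_type(self, etype: EntityType) -> list[str]:
        return sorted(e for e, ty in self.entities.items() if ty == etype)

    def to_networkx(self) -> nx.Graph:
        """Undirected simple graph over all entities; multi-edges collapsed.

        Each edge carries ``triples``: the list of WeightedTriples linking the
        pair in either orientation.
        """
        g = nx.Graph()
        for e, ty in self.entities.items():
            g.add_node(e, entity_type=ty)
        for t in self.triples:
            if g.has_edge(t.head, t.tail):
                g[t.head][t.tail]["triples"].append(t)
            else:
                g.add_edge(t.head, t.tail, triples=[t])
        return g

    def induced_subgraph(self, keep: set[str]) -> "KnowledgeGraph":
        entities = {e: ty for e, ty in self.entities.items() if e in keep}
        triples = [t for t in self.triples if t.head in keep and t.tail in keep]
        return KnowledgeGraph(entities=entities, triples=triples, vocabulary=self.vocabulary)


@dataclass
class GoldStandardIndications:
    """Curated (drug, disease) treatment pairs used as evaluation positives."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)

    @property
    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self.pairs})

    @property
    def diseases(self) -> list[str]:
        return sorted({z for _, z in self.pairs})

    def unordered(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in self.pairs}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DataSplit:
    """Disjoint train/validation/test triple lists whose union is the input."""

    train: list[WeightedTriple]
    validation: list[WeightedTriple]
    test: list[WeightedTriple]
    seed: int

    def all_triples(self) -> list[WeightedTriple]:
        return self.train + self.validation + self.test


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_GRAPH_COLUMNS = ["head", "head_type", "theme", "tail", "tail_type", "support"]


def read_graph(path: str | Path, vocabulary: list[Theme] | None = None) -> KnowledgeGraph:
    """Read a graph from TSV with columns head, head_type, theme, tail,
    tail_type, support.  Lines starting with '#' are ignored.

    Raises :class:`GraphParseError` naming the offending line on unknown
    entity types, unknown theme codes, or supports outside [0, 1].
    """
    if vocabulary is None:
        from .themes import default_vocabulary

        vocabulary = default_vocabulary()
    known_codes = {t.code for t in vocabulary}
    entities: dict[str, EntityType] = {}
    triples: list[WeightedTriple] = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields != _GRAPH_COLUMNS:
                    raise GraphParseError(
                        f"line {lineno}: expected header {_GRAPH_COLUMNS}, got {fields}"
                    )
                header = fields
                continue
            if len(fields) != len(_GRAPH_COLUMNS):
                raise GraphParseError(
                    f"line {lineno}: expected {len(_GRAPH_COLUMNS)} columns, got {len(fields)}"
                )
            head, head_type, theme, tail, tail_type, support_s = fields
            try:
                htype = EntityType(head_type)
                ttype = EntityType(tail_type)
            except ValueError as exc:
                raise GraphParseError(f"line {lineno}: {exc}") from exc
            if theme not in known_codes:
                raise GraphParseError(f"line {lineno}: unknown theme code {theme!r}")
            try:
                support = float(support_s)
            except ValueError as exc:
                raise GraphParseError(
                    f"line {lineno}: unparseable support {support_s!r}"
                ) from exc
            for ent, ty in ((head, htype), (tail, ttype)):
                prev = entities.setdefault(ent, ty)
                if prev != ty:
                    raise GraphParseError(
                        f"line {lineno}: entity {ent!r} retyped {prev.value} -> {ty.value}"
                    )
            try:
                triples.append(WeightedTriple(head=head, theme=theme, tail=tail, support=support))
            except ValueError as exc:
                raise GraphParseError(f"line {lineno}: {exc}") from exc
    return KnowledgeGraph(entities=entities, triples=triples, vocabulary=vocabulary)


def write_graph(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write a graph as TSV, rows sorted by (head, theme, tail); supports are
    serialized losslessly (17 significant digits)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_GRAPH_COLUMNS) + "\n")
        for t in sorted(graph.triples, key=lambda t: (t.head, t.theme, t.tail)):
            fh.write(
                "\t".join(
                    [
                        t.head,
                        graph.entities[t.head].value,
                        t.theme,
                        t.tail,
                        graph.entities[t.tail].value,
                        f"{t.support:.17g}",
                    ]
                )
                + "\n"
            )


def read_gold_standard(path: str | Path) -> GoldStandardIndications:
    """Read a two-column (drug, disease) TSV gold-standard indication list."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if fields == ["drug", "disease"]:
                    continue  # header row; otherwise treat as data
            if len(fields) != 2:
                raise GraphParseError(f"expected 2 columns, got {fields!r}")
            pairs.add((fields[0], fields[1]))
    return GoldStandardIndications(pairs=pairs)


def write_gold_standard(gold: GoldStandardIndications, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("drug\tdisease\n")
        for drug, disease in sorted(gold.pairs):
            fh.write(f"{drug}\t{disease}\n")


# ---------------------------------------------------------------------------
# Graph filtering
# ---------------------------------------------------------------------------


def largest_connected_component(graph: KnowledgeGraph) -> KnowledgeGraph:
    """Induced subgraph on the largest undirected connected component.

    Entities without edges count as singleton components.  Ties between
    equally-sized components go to the one containing the lexicographically
    smallest entity id.
    """
    if not graph.entities:
        raise ValueError("empty graph has no connected component")
    g = graph.to_networkx()
    best = min(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return graph.induced_subgraph(set(best))


def filter_for_repurposing(
    graph: KnowledgeGraph,
    priority_diseases: set[str],
    indication_nodes: set[str],
) -> KnowledgeGraph:
    """Keep only gene nodes, high-priority disease nodes, and drug/disease
    nodes appearing in a known indication; then take the largest connected
    component of the remainder."""
    unknown = (set(priority_diseases) | set(indication_nodes)) - set(graph.entities)
    if unknown:
        raise ValueError(f"ids not in graph: {sorted(unknown)[:5]}")
    keep = {
        e
        for e, ty in graph.entities.items()
        if ty == EntityType.GENE or e in priority_diseases or e in indication_nodes
    }
    filtered = graph.induced_subgraph(keep)
    if not filtered.entities:
        raise ValueError("no nodes survive the repurposing filter")
    return largest_connected_component(filtered)


SUBMODEL_VARIANTS = ("full", "treatment_only_drdz", "no_genes", "treatment_edges_only")


def _is_drug_disease(graph: KnowledgeGraph, t: WeightedTriple) -> bool:
    return {graph.entities[t.head], graph.entities[t.tail]} == {
        EntityType.DRUG,
        EntityType.DISEASE,
    }


def build_submodel(graph: KnowledgeGraph, variant: str) -> KnowledgeGraph:
    """Ablation submodels of the training graph.

    ``full``
        the graph unchanged.
    ``treatment_only_drdz``
        drop drug-disease triples whose theme is not "T"; all other
        categories kept.
    ``no_genes``
        drop every triple touching a gene, then take the largest connected
        component of the drug-disease bipartite remainder.
    ``treatment_edges_only``
        keep only (drug, "T", disease) triples — the no-embedding baseline
        scored directly by support.
    """
    if variant not in SUBMODEL_VARIANTS:
        raise ValueError(f"unknown submodel variant {variant!r}")
    if variant == "full":
        return KnowledgeGraph(
            entities=dict(graph.entities),
            triples=list(graph.triples),
            vocabulary=graph.vocabulary,
        )
    if variant == "treatment_only_drdz":
        triples = [
            t
            for t in graph.triples
            if not (_is_drug_disease(graph, t) and t.theme != "T")
        ]
        return KnowledgeGraph(
            entities=dict(graph.entities), triples=triples, vocabulary=graph.vocabulary
        )
    if variant == "no_genes":
        triples = [
            t
            for t in graph.triples
            if graph.entities[t.head] != EntityType.GENE
            and graph.entities[t.tail] != EntityType.GENE
        ]
        entities = {e: ty for e, ty in graph.entities.items() if ty != EntityType.GENE}
        bipartite = KnowledgeGraph(
            entities=entities, triples=triples, vocabulary=graph.vocabulary
        )
        return largest_connected_component(bipartite)
    # treatment_edges_only
    triples = [t for t in graph.triples if _is_drug_disease(graph, t) and t.theme == "T"]
    keep = {e for t in triples for e in (t.head, t.tail)}
    return KnowledgeGraph(
        entities={e: ty for e, ty in graph.entities.items() if e in keep},
        triples=triples,
        vocabulary=graph.vocabulary,
    )


# ---------------------------------------------------------------------------
# Train/validation/test splitting
# ---------------------------------------------------------------------------


def _allocate(n: int, fracs: tuple[float, float, float]) -> tuple[int, int, int]:
    # floor allocation for validation/test, remainder to train
    n_val = int(math.floor(fracs[1] * n))
    n_test = int(math.floor(fracs[2] * n))
    return n - n_val - n_test, n_val, n_test


def split_triples(
    graph: KnowledgeGraph,
    gold: GoldStandardIndications,
    indication_fracs: tuple[float, float, float] = (0.6, 0.2, 0.2),
    background_fracs: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
    by_pair: bool = False,
) -> DataSplit:
    """Stratified split: triples whose unordered (head, tail) pair is a known
    indication are split by ``indication_fracs`` (default 60/20/20); all other
    triples by ``background_fracs`` (default 90/5/5).

    With ``by_pair=True`` all indication-containing triples of one pair land
    in the same fold.  Deterministic given ``seed``.
    """
    for name, fracs in (("indication", indication_fracs), ("background", background_fracs)):
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValueError(f"{name} fractions must sum to 1, got {fracs}")
    gold_unordered = gold.unordered()
    indication = [t for t in graph.triples if t.pair in gold_unordered]
    background = [t for t in graph.triples if t.pair not in gold_unordered]
    rng = np.random.default_rng(seed)

    folds: dict[str, list[WeightedTriple]] = {"train": [], "validation": [], "test": []}

    def _split_stratum(triples: list[WeightedTriple], fracs, label: str) -> None:
        if not triples:
            return
        if len(triples) < 3:
            raise ValueError(
                f"{label} stratum has only {len(triples)} triples; need >= 3"
            )
        order = rng.permutation(len(triples))
        shuffled = [triples[i] for i in order]
        n_train, n_val, n_test = _allocate(len(shuffled), fracs)
        folds["train"].extend(shuffled[:n_train])
        folds["validation"].extend(shuffled[n_train : n_train + n_val])
        folds["test"].extend(shuffled[n_train + n_val :])

    if by_pair and indication:
        groups: dict[frozenset[str], list[WeightedTriple]] = {}
        for t in indication:
            groups.setdefault(t.pair, []).append(t)
        keys = sorted(groups, key=sorted)
        if len(keys) < 3:
            raise ValueError(f"indication stratum has only {len(keys)} pairs; need >= 3")
        order = rng.permutation(len(keys))
        shuffled_keys = [keys[i] for i in order]
        n_train, n_val, n_test = _allocate(len(keys), indication_fracs)
        for fold, chunk in zip(
            ("train", "validation", "test"),
            (
                shuffled_keys[:n_train],
                shuffled_keys[n_train : n_train + n_val],
                shuffled_keys[n_train + n_val :],
            ),
        ):
            for key in chunk:
                folds[fold].extend(groups[key])
    else:
        _split_stratum(indication, indication_fracs, "indication")
    _split_stratum(background, background_fracs, "background")

    return DataSplit(
        train=folds["train"],
        validation=folds["validation"],
        test=folds["test"],
        seed=seed,
    )
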