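"""Graph data model, I/O, filtering, submodels and splits."""

import numpy as np
import pytest

from ukge.kg import (
    EntityType,
    GoldStandardIndications,
    GraphParseError,
    KnowledgeGraph,
    WeightedTriple,
    build_submodel,
    filter_for_repurposing,
    largest_connected_component,
    read_graph,
    split_triples,
    write_graph,
)
from conftest import random_graph


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


def test_vocabulary_has_32_distinct_codes(vocabulary):
    codes = {t.code for t in vocabulary}
    assert len(codes) == 32
    # some codes legitimately belong to several categories
    assert len(vocabulary) > len(codes)
    cats = {t.category for t in vocabulary}
    assert cats == {"Dr-Dz", "Dr-G", "Dz-G", "G-G"}


@pytest.mark.parametrize("support", [-0.1, 1.2, float("nan")])
def test_support_outside_unit_interval_rejected(support):
    with pytest.raises(ValueError):
        WeightedTriple("a", "T", "b", support)


def test_self_loop_rejected():
    with pytest.raises(ValueError):
        WeightedTriple("a", "T", "a", 0.5)


def test_theme_type_compatibility_enforced(vocabulary):
    entities = {"d0": EntityType.DRUG, "g0": EntityType.GENE}
    # "T" is a drug-disease theme; a drug-gene edge cannot carry it
    with pytest.raises(ValueError, match="incompatible"):
        KnowledgeGraph(
            entities=entities,
            triples=[WeightedTriple("d0", "T", "g0", 0.5)],
            vocabulary=vocabulary,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def test_read_minimal_file(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text(
        "head\thead_type\ttheme\ttail\ttail_type\tsupport\n"
        "# a comment\n"
        "aspirin\tdrug\tT\theadache\tdisease\t0.95\n"
    )
    g = read_graph(p)
    assert len(g.entities) == 2
    assert len(g.triples) == 1
    assert g.triples[0].support == 0.95


@pytest.mark.parametrize(
    "row,message",
    [
        ("a\tdrug\tT\tb\tdisease\t1.2", "line 2"),
        ("a\tdrug\tT\tb\tdisease\tnot_a_number", "line 2"),
        ("a\tpotion\tT\tb\tdisease\t0.5", "line 2"),
        ("a\tdrug\tQQQ\tb\tdisease\t0.5", "unknown theme"),
    ],
)
def test_malformed_rows_error_with_line_number(tmp_path, row, message):
    p = tmp_path / "g.tsv"
    p.write_text("head\thead_type\ttheme\ttail\ttail_type\tsupport\n" + row + "\n")
    with pytest.raises(GraphParseError, match=message):
        read_graph(p)


def test_write_empty_graph_is_header_only(tmp_path, vocabulary):
    g = KnowledgeGraph(entities={}, triples=[], vocabulary=vocabulary)
    p = tmp_path / "g.tsv"
    write_graph(g, p)
    assert p.read_text().strip() == "head\thead_type\ttheme\ttail\ttail_type\tsupport"


def test_roundtrip_preserves_triples_exactly(tmp_path, rng):
    for i in range(10):
        g = random_graph(rng, n_edges=30)
        p = tmp_path / f"g{i}.tsv"
        write_graph(g, p)
        back = read_graph(p)
        # the TSV is an edge list: triples survive exactly, and every
        # connected entity keeps its type (isolated nodes have no row)
        connected = {e for t in g.triples for e in (t.head, t.tail)}
        assert back.entities == {e: g.entities[e] for e in connected}
        assert sorted(back.triples) == sorted(g.triples)


# ---------------------------------------------------------------------------
# connectivity / filtering
# ---------------------------------------------------------------------------


def _bfs_components(graph):
    """Brute-force BFS component labelling over the undirected edge set."""
    adj = {e: set() for e in graph.entities}
    for t in graph.triples:
        adj[t.head].add(t.tail)
        adj[t.tail].add(t.head)
    seen, comps = set(), []
    for start in graph.entities:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def test_lcc_of_connected_graph_is_identity(tiny_graph):
    out = largest_connected_component(tiny_graph)
    assert out.entities == tiny_graph.entities
    assert sorted(out.triples) == sorted(tiny_graph.triples)


def test_lcc_picks_larger_component(vocabulary):
    entities = {
        "d0": EntityType.DRUG, "z0": EntityType.DISEASE, "g0": EntityType.GENE,
        "d1": EntityType.DRUG, "z1": EntityType.DISEASE,
    }
    triples = [
        WeightedTriple("d0", "T", "z0", 0.9),
        WeightedTriple("z0", "U", "g0", 0.5),
        WeightedTriple("d1", "T", "z1", 0.9),
    ]
    g = KnowledgeGraph(entities=entities, triples=triples, vocabulary=vocabulary)
    out = largest_connected_component(g)
    assert set(out.entities) == {"d0", "z0", "g0"}


def test_lcc_empty_graph_errors(vocabulary):
    with pytest.raises(ValueError):
        largest_connected_component(
            KnowledgeGraph(entities={}, triples=[], vocabulary=vocabulary)
        )


def test_lcc_matches_bfs_oracle_on_random_graphs(rng):
    for _ in range(100):
        g = random_graph(
            rng,
            n_drugs=int(rng.integers(2, 8)),
            n_diseases=int(rng.integers(2, 8)),
            n_genes=int(rng.integers(2, 12)),
            n_edges=int(rng.integers(5, 35)),
        )
        comps = _bfs_components(g)
        best = min(comps, key=lambda c: (-len(c), min(c)))
        assert set(largest_connected_component(g).entities) == best


def test_filter_for_repurposing_matches_setfilter_then_bfs_oracle(rng):
    for _ in range(50):
        g = random_graph(rng, n_edges=40)
        ents = sorted(g.entities)
        diseases = [e for e in ents if g.entities[e] == EntityType.DISEASE]
        others = [e for e in ents if g.entities[e] != EntityType.GENE]
        priority = {e for e in diseases if rng.random() < 0.4}
        indication = {e for e in others if rng.random() < 0.4}
        keep = {
            e for e, ty in g.entities.items()
            if ty == EntityType.GENE or e in priority or e in indication
        }
        sub = g.induced_subgraph(keep)
        comps = _bfs_components(sub)
        expected = min(comps, key=lambda c: (-len(c), min(c))) if comps else set()
        if not keep:
            with pytest.raises(ValueError):
                filter_for_repurposing(g, priority, indication)
            continue
        out = filter_for_repurposing(g, priority, indication)
        assert set(out.entities) == expected


def test_filter_drug_without_indication_removed(tiny_graph):
    out = filter_for_repurposing(tiny_graph, {"headache"}, set())
    assert "aspirin" not in out.entities


# ---------------------------------------------------------------------------
# submodels
# ---------------------------------------------------------------------------


def test_submodel_full_is_identity(tiny_graph):
    out = build_submodel(tiny_graph, "full")
    assert sorted(out.triples) == sorted(tiny_graph.triples)


def test_submodel_no_genes_drops_gene_triples(tiny_graph):
    out = build_submodel(tiny_graph, "no_genes")
    assert all(
        EntityType.GENE not in (out.entities[t.head], out.entities[t.tail])
        for t in out.triples
    )
    assert "ptgs2" not in out.entities


def test_submodel_unknown_variant_errors(tiny_graph):
    with pytest.raises(ValueError):
        build_submodel(tiny_graph, "bogus")


def test_submodel_treatment_filters_match_brute_force(rng):
    for _ in range(30):
        g = random_graph(rng, n_edges=50)

        def is_drdz(t):
            return {g.entities[t.head], g.entities[t.tail]} == {
                EntityType.DRUG,
                EntityType.DISEASE,
            }

        only = build_submodel(g, "treatment_only_drdz")
        expected = [t for t in g.triples if not (is_drdz(t) and t.theme != "T")]
        assert sorted(only.triples) == sorted(expected)

        baseline = build_submodel(g, "treatment_edges_only")
        expected_t = [t for t in g.triples if is_drdz(t) and t.theme == "T"]
        assert sorted(baseline.triples) == sorted(expected_t)
        # baseline is the Dr-Dz restriction of the treatment-only submodel
        assert set(baseline.triples) <= set(only.triples)


def test_submodels_never_add_triples(rng):
    g = random_graph(rng, n_edges=40)
    for variant in ("full", "treatment_only_drdz", "no_genes", "treatment_edges_only"):
        assert set(build_submodel(g, variant).triples) <= set(g.triples)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def test_split_partitions_input(rng):
    g = random_graph(rng, n_edges=60)
    gold = GoldStandardIndications(
        pairs={(t.head, t.tail) for t in g.triples[:5]}
    )
    split = split_triples(g, gold, seed=7)
    together = split.train + split.validation + split.test
    assert sorted(together) == sorted(g.triples)
    assert len(set(map(id, together))) == len(together)


def test_split_empty_gold_uses_background_fractions(rng):
    g = random_graph(rng, n_edges=100)
    split = split_triples(g, GoldStandardIndications(pairs=set()), seed=3)
    assert abs(len(split.validation) - 5) <= 1
    assert abs(len(split.test) - 5) <= 1


def test_split_deterministic_given_seed(rng):
    g = random_graph(rng, n_edges=80)
    gold = GoldStandardIndications(pairs={(t.head, t.tail) for t in g.triples[:8]})
    a = split_triples(g, gold, seed=11)
    b = split_triples(g, gold, seed=11)
    assert a.train == b.train and a.validation == b.validation and a.test == b.test
    c = split_triples(g, gold, seed=12)
    assert a.train != c.train


def test_split_stratum_sizes_within_one(vocabulary, rng):
    # 1000 triples, 100 of them indication-containing
    drugs = {f"d{i}": EntityType.DRUG for i in range(100)}
    diseases = {f"z{i}": EntityType.DISEASE for i in range(100)}
    entities = drugs | diseases
    triples = [
        WeightedTriple(f"d{i % 100}", "T", f"z{(i * 7) % 100}", 0.5)
        for i in range(1000)
    ]
    # dedupe (head, theme, tail) via varying support is unnecessary: pairs repeat
    # over i so build distinct pairs instead
    triples = []
    k = 0
    for i in range(100):
        for j in range(10):
            triples.append(WeightedTriple(f"d{i}", "T", f"z{(i + j * 11) % 100}", 0.5))
            k += 1
    g = KnowledgeGraph(entities=entities, triples=triples, vocabulary=vocabulary)
    gold_pairs = {(t.head, t.tail) for t in triples[:100]}
    assert len(gold_pairs) == 100
    gold = GoldStandardIndications(pairs=gold_pairs)
    split = split_triples(g, gold, seed=0)
    unordered = gold.unordered()
    n_ind = sum(1 for t in triples if t.pair in unordered)
    for fold, ind_frac, bg_frac in (
        (split.train, 0.6, 0.9),
        (split.validation, 0.2, 0.05),
        (split.test, 0.2, 0.05),
    ):
        got_ind = sum(1 for t in fold if t.pair in unordered)
        got_bg = len(fold) - got_ind
        assert abs(got_ind - ind_frac * n_ind) <= 1
        assert abs(got_bg - bg_frac * (len(triples) - n_ind)) <= 1


def test_split_small_stratum_errors(rng):
    g = random_graph(rng, n_edges=10)
    gold = GoldStandardIndications(pairs={(g.triples[0].head, g.triples[0].tail)})
    with pytest.raises(ValueError, match="stratum"):
        split_triples(g, gold, seed=0)


def test_split_by_pair_keeps_pairs_in_one_fold(rng, vocabulary):
    entities = {f"d{i}": EntityType.DRUG for i in range(10)} | {
        f"z{i}": EntityType.DISEASE for i in range(10)
    }
    triples = []
    for i in range(10):
        for code in ("T", "Pa", "Sa"):
            triples.append(WeightedTriple(f"d{i}", code, f"z{i}", 0.5))
    g = KnowledgeGraph(entities=entities, triples=triples, vocabulary=vocabulary)
    gold = GoldStandardIndications(pairs={(f"d{i}", f"z{i}") for i in range(10)})
    split = split_triples(g, gold, seed=5, by_pair=True)
    for fold in (split.train, split.validation, split.test):
        pairs = {t.pair for t in fold}
        for t in g.triples:
            if t.pair in pairs:
                assert t in fold
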