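import numpy as np
import pytest

from ukge.kg import EntityType, KnowledgeGraph, WeightedTriple
from ukge.themes import default_vocabulary


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture
def tiny_graph(vocabulary):
    """One drug treating one disease via one gene link."""
    entities = {
        "aspirin": EntityType.DRUG,
        "headache": EntityType.DISEASE,
        "ptgs2": EntityType.GENE,
    }
    triples = [
        WeightedTriple("aspirin", "T", "headache", 0.95),
        WeightedTriple("aspirin", "N", "ptgs2", 0.8),
        WeightedTriple("headache", "U", "ptgs2", 0.4),
    ]
    return KnowledgeGraph(entities=entities, triples=triples, vocabulary=vocabulary)


def random_graph(rng, n_drugs=5, n_diseases=5, n_genes=10, n_edges=40, vocabulary=None):
    """A random typed multigraph with valid themes; not necessarily connected."""
    if vocabulary is None:
        vocabulary = default_vocabulary()
    by_cat = {}
    for th in vocabulary:
        by_cat.setdefault(th.category, []).append(th.code)
    drugs = [f"d{i}" for i in range(n_drugs)]
    diseases = [f"z{i}" for i in range(n_diseases)]
    genes = [f"g{i}" for i in range(n_genes)]
    entities = (
        {d: EntityType.DRUG for d in drugs}
        | {z: EntityType.DISEASE for z in diseases}
        | {g: EntityType.GENE for g in genes}
    )
    cat_pairs = {
        "Dr-Dz": (drugs, diseases),
        "Dr-G": (drugs, genes),
        "Dz-G": (diseases, genes),
        "G-G": (genes, genes),
    }
    seen = set()
    triples = []
    while len(triples) < n_edges:
        cat = list(cat_pairs)[int(rng.integers(4))]
        heads, tails = cat_pairs[cat]
        h = heads[int(rng.integers(len(heads)))]
        t = tails[int(rng.integers(len(tails)))]
        if h == t:
            continue
        code = by_cat[cat][int(rng.integers(len(by_cat[cat])))]
        if (h, code, t) in seen or (t, code, h) in seen:
            continue
        seen.add((h, code, t))
        triples.append(WeightedTriple(h, code, t, float(rng.random())))
    return KnowledgeGraph(entities=entities, triples=triples, vocabulary=vocabulary)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
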