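"""Synthetic support-scored knowledge graphs with planted structure.

The generator emulates a literature-mined graph: drug, disease and gene
entities connected by themed edges in the four GNBR-style categories, with
supports produced by a planted bilinear model.  Every entity i has a latent
vector z_i and every theme a latent vector r; a candidate edge (h, r, t)
receives support

    s = clamp(w_true * (r . (z_h o z_t)) + b_true + eps, 0, 1),
    eps ~ N(0, noise_sd^2)

so a bilinear embedding model of matching dimension can in principle recover
the supports exactly (up to noise).  A chosen number of (drug, disease)
pairs — those with the highest noise-free "T" (treatment) score — are
planted as ground-truth indications and forced into the edge set.

Two features of literature-mined graphs are emulated deliberately:

* a random entity pair is usually unrelated — (w_true, b_true) are
  calibrated per graph so the median candidate edge scores ~0.2 while the
  weakest planted treatment pair scores 0.92, keeping the assumption
  behind tail-corrupted negative sampling (arbitrary triples have support
  near 0) approximately true;
* related pairs are the ones that get written about — a candidate edge's
  inclusion probability is proportional to its noise-free support, with
  the per-category expected edge count held at edge_density x pair count.

Planted treatment edges are stored noise-free, which keeps their support
>= 0.9 by construction; all other edges carry Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kg import (
    EntityType,
    GoldStandardIndications,
    KnowledgeGraph,
    Theme,
    WeightedTriple,
)
from .themes import default_vocabulary


@dataclass
class SyntheticConfig:
    """Shape and noise parameters of the generated graph.

    Defaults give a desk-scale graph (90 entities, ~700 edges) whose planted
    treatment pairs are recoverable by an 8-dimensional embedding.
    """

    n_drugs: int = 20
    n_diseases: int = 20
    n_genes: int = 50
    latent_dim: int = 8
    n_themes_per_category: int = 3
    edge_density: float = 0.8
    noise_sd: float = 0.05
    n_planted_indications: int = 30
    seed: int = 0
    n_clusters: int = 5
    cluster_sd: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_diseases, self.n_genes) <= 0:
            raise ValueError("entity counts must be positive")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_planted_indications < 0:
            raise ValueError("n_planted_indications must be nonnegative")
        if self.n_themes_per_category < 1:
            raise ValueError("need at least one theme per category")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated graph."""

    entity_ids: list[str]
    entity_vectors: np.ndarray          # n x latent_dim
    relation_codes: list[str]
    relation_vectors: np.ndarray        # m x latent_dim
    w_true: float
    b_true: float
    planted_pairs: GoldStandardIndications
    _eindex: dict[str, int] = field(init=False, repr=False)
    _rindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._eindex = {e: i for i, e in enumerate(self.entity_ids)}
        self._rindex = {r: i for i, r in enumerate(self.relation_codes)}

    def plausibility(self, head: str, theme: str, tail: str) -> float:
        h = self.entity_vectors[self._eindex[head]]
        t = self.entity_vectors[self._eindex[tail]]
        r = self.relation_vectors[self._rindex[theme]]
        return float(np.dot(r, h * t))

    def noise_free_support(self, head: str, theme: str, tail: str) -> float:
        return float(
            np.clip(self.w_true * self.plausibility(head, theme, tail) + self.b_true, 0.0, 1.0)
        )


def _inclusion_probabilities(scores: np.ndarray, density: float) -> np.ndarray:
    """Per-pair inclusion probabilities proportional to a floor-clipped
    noise-free support, normalised so the expected edge count equals
    density x pair count (probabilities capped at 1 with the excess mass
    redistributed)."""
    weights = np.maximum(scores, 0.05)
    n = scores.size
    target = density * n
    probs = np.zeros(n)
    capped = np.zeros(n, dtype=bool)
    for _ in range(100):
        free = ~capped
        remaining = target - capped.sum()
        if remaining <= 0 or not free.any():
            break
        probs[free] = remaining * weights[free] / weights[free].sum()
        newly = free & (probs > 1.0)
        if not newly.any():
            break
        capped |= newly
    probs[capped] = 1.0
    return np.clip(probs, 0.0, 1.0)


# Canonical head/tail types per category (head type listed first).
_CATEGORY_ORIENTATION: dict[str, tuple[EntityType, EntityType]] = {
    "Dr-Dz": (EntityType.DRUG, EntityType.DISEASE),
    "Dr-G": (EntityType.DRUG, EntityType.GENE),
    "Dz-G": (EntityType.DISEASE, EntityType.GENE),
    "G-G": (EntityType.GENE, EntityType.GENE),
}


def _category_themes(n_per_category: int) -> list[Theme]:
    """First n themes of each category from the default vocabulary ("T" is
    always the first drug-disease theme)."""
    chosen: list[Theme] = []
    for category in _CATEGORY_ORIENTATION:
        in_cat = [t for t in default_vocabulary() if t.category == category]
        if n_per_category > len(in_cat):
            raise ValueError(
                f"category {category} has only {len(in_cat)} themes in the vocabulary"
            )
        chosen.extend(in_cat[:n_per_category])
    return chosen


def generate_kg(config: SyntheticConfig) -> tuple[KnowledgeGraph, SyntheticTruth]:
    """Draw a support-scored heterogeneous graph from the planted bilinear
    model; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    drugs = [f"drug{i:03d}" for i in range(config.n_drugs)]
    diseases = [f"disease{i:03d}" for i in range(config.n_diseases)]
    genes = [f"gene{i:03d}" for i in range(config.n_genes)]
    entity_ids = drugs + diseases + genes
    entity_types = (
        {e: EntityType.DRUG for e in drugs}
        | {e: EntityType.DISEASE for e in diseases}
        | {e: EntityType.GENE for e in genes}
    )
    themes = _category_themes(config.n_themes_per_category)
    relation_codes = sorted({t.code for t in themes})

    # Community-structured latents: each entity sits near one of n_clusters
    # type-specific centres (drug classes, disease families, gene modules),
    # with cluster_sd controlling individual deviation from the centre.
    counts = (config.n_drugs, config.n_diseases, config.n_genes)
    blocks = []
    for n_type in counts:
        centres = rng.normal(size=(config.n_clusters, config.latent_dim))
        assign = rng.integers(config.n_clusters, size=n_type)
        blocks.append(
            centres[assign]
            + config.cluster_sd * rng.normal(size=(n_type, config.latent_dim))
        )
    Z = np.vstack(blocks)
    Rv = rng.normal(size=(len(relation_codes), config.latent_dim))
    eindex = {e: i for i, e in enumerate(entity_ids)}
    rindex = {c: i for i, c in enumerate(relation_codes)}

    # Noise-free treatment plausibility of every (drug, disease) pair.
    r_T = Rv[rindex["T"]]
    g_T = np.einsum("k,ik,jk->ij", r_T, Z[: config.n_drugs],
                    Z[config.n_drugs : config.n_drugs + config.n_diseases])
    flat = np.sort(g_T.ravel())
    n_plant = min(config.n_planted_indications, flat.size)
    g_zero = float(flat[int(0.80 * (flat.size - 1))])
    if n_plant > 0:
        g_ref = float(flat[-n_plant])
    else:
        g_ref = float(flat[int(0.95 * (flat.size - 1))])
    if g_ref <= g_zero:
        raise ValueError(
            "degenerate configuration: planted pairs are not in the top fifth "
            "of treatment scores (reduce n_planted_indications)"
        )
    # 80th-percentile candidate -> 0 (so ~80% of random pairs clamp to
    # support 0, emulating the overwhelming unrelatedness of random pairs
    # in a literature graph); weakest planted treatment pair -> 0.92
    w_true = 0.92 / (g_ref - g_zero)
    b_true = -w_true * g_zero

    # Planted indications: the n highest noise-free treatment scores.
    order = np.argsort(g_T.ravel())[::-1][:n_plant]
    planted = set()
    for k in order:
        i, j = divmod(int(k), config.n_diseases)
        planted.add((drugs[i], diseases[j]))

    # Sample themed edges per category with inclusion probability
    # proportional to each (pair, theme) candidate's noise-free support
    # (related pairs get written about), at expected edge count
    # density x pair count.  Because every theme of a pair shares the same
    # h o t interaction, a strongly related pair tends to acquire several
    # correlated themed edges, as in real literature graphs.
    members = {
        EntityType.DRUG: drugs,
        EntityType.DISEASE: diseases,
        EntityType.GENE: genes,
    }
    edges: dict[tuple[str, str, str], float] = {}
    for category, (htype, ttype) in _CATEGORY_ORIENTATION.items():
        codes = [t.code for t in themes if t.category == category]
        heads, tails = members[htype], members[ttype]
        if htype == ttype:
            pairs = [(a, b) for i, a in enumerate(heads) for b in heads[i + 1 :]]
        else:
            pairs = [(a, b) for a in heads for b in tails]
        interact = np.array(
            [Z[eindex[h]] * Z[eindex[t]] for h, t in pairs]
        )  # n_pairs x k
        g_all = interact @ Rv[[rindex[c] for c in codes]].T  # n_pairs x n_themes
        clean = np.clip(w_true * g_all + b_true, 0.0, 1.0)
        probs = _inclusion_probabilities(
            clean.ravel(), config.edge_density / len(codes)
        ).reshape(clean.shape)
        uniforms = rng.random(clean.shape)
        noise = rng.normal(0.0, config.noise_sd, size=clean.shape)
        for p, (head, tail) in enumerate(pairs):
            for ti, code in enumerate(codes):
                if uniforms[p, ti] >= probs[p, ti]:
                    continue
                s = float(np.clip(clean[p, ti] + noise[p, ti], 0.0, 1.0))
                edges[(head, code, tail)] = s

    # Force planted treatment edges in, noise-free (support >= 0.9 by
    # calibration); overwrite any sampled noisy "T" edge on the same pair.
    for drug, disease in sorted(planted):
        g = float(np.dot(r_T, Z[eindex[drug]] * Z[eindex[disease]]))
        edges[(drug, "T", disease)] = float(np.clip(w_true * g + b_true, 0.0, 1.0))

    if not any(
        {entity_types[h], entity_types[t]} == {EntityType.DRUG, EntityType.DISEASE}
        for (h, _, t) in edges
    ):
        raise ValueError("edge density too low: no drug-disease edges generated")

    triples = [
        WeightedTriple(head=h, theme=c, tail=t, support=s)
        for (h, c, t), s in sorted(edges.items())
    ]
    graph = KnowledgeGraph(entities=entity_types, triples=triples, vocabulary=themes)
    truth = SyntheticTruth(
        entity_ids=entity_ids,
        entity_vectors=Z,
        relation_codes=relation_codes,
        relation_vectors=Rv,
        w_true=w_true,
        b_true=b_true,
        planted_pairs=GoldStandardIndications(pairs=planted),
    )
    return graph, truth


def write_truth(truth: SyntheticTruth, prefix: str | Path) -> None:
    """Sidecar TSVs: latent entity/relation vectors and scalar metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.entity_vectors, index=pd.Index(truth.entity_ids, name="id")).to_csv(
        f"{prefix}.entity_latents.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(
        truth.relation_vectors, index=pd.Index(truth.relation_codes, name="id")
    ).to_csv(f"{prefix}.relation_latents.tsv", sep="\t", float_format="%.17g")
    with open(f"{prefix}.scalars.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"w_true\t{truth.w_true:.17g}\n")
        fh.write(f"b_true\t{truth.b_true:.17g}\n")


# ---------------------------------------------------------------------------
# Proximity fixture
# ---------------------------------------------------------------------------


def generate_proximity_fixture(
    n_proteins: int,
    dim: int,
    effect: float,
    set_sizes: tuple[int, int],
    seed: int = 0,
) -> tuple["pd.DataFrame", list[str], list[str]]:
    """A protein-embedding matrix plus two gene sets for the proximity test.

    With ``effect=0`` both sets are draws with replacement from all proteins
    — exchangeable with the permutation null, so empirical p-values are
    uniform.  With ``effect>0`` the members of both sets are shifted along a
    common latent direction by ``effect`` units, inflating their median
    cosine similarity above the null.

    Returns (embedding DataFrame indexed by protein id, set A ids, set B ids).
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    a, b = set_sizes
    if a <= 0 or b <= 0:
        raise ValueError("set sizes must be positive")
    if max(a, b) > n_proteins:
        raise ValueError("set sizes cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    ids = [f"prot{i:04d}" for i in range(n_proteins)]
    X = rng.normal(size=(n_proteins, dim))
    if effect > 0:
        if a + b > n_proteins:
            raise ValueError("disjoint member sets need a + b <= n_proteins")
        direction = rng.normal(size=dim)
        direction /= np.linalg.norm(direction)
        chosen = rng.choice(n_proteins, size=a + b, replace=False)
        X[chosen] += effect * direction
        set_a = [ids[i] for i in chosen[:a]]
        set_b = [ids[i] for i in chosen[a:]]
    else:
        set_a = [ids[i] for i in rng.integers(n_proteins, size=a)]
        set_b = [ids[i] for i in rng.integers(n_proteins, size=b)]
    emb = pd.DataFrame(X, index=pd.Index(ids, name="id"))
    return emb, set_a, set_b
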