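"""Treatment-link scoring and gold-standard evaluation.

Candidate (drug, disease) pairs are ranked by the unbounded test-time score
under the treatment theme "T".  Evaluation against gold-standard indications
follows the standard protocol: known indications as positives, randomly
recombined drug-disease pairs (drawn from the gold-standard universes) as
negatives, summarised by ROC and precision-recall curves.  Theme-level
analyses — pairwise cosine similarity of relation embeddings with
hierarchical clustering, and per-theme precision at fixed recall — probe
which semantic themes carry treatment signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn import metrics

from .kg import GoldStandardIndications, KnowledgeGraph
from .model import EmbeddingModel

TREATMENT_THEME = "T"


@dataclass(frozen=True)
class RankedCandidate:
    drug: str
    disease: str
    score: float
    rank: int


def score_treatment_candidates(
    model: EmbeddingModel,
    drugs: list[str],
    diseases: list[str],
    exclude: GoldStandardIndications | None = None,
) -> list[RankedCandidate]:
    """Score every drug x disease pair not in ``exclude`` with the unbounded
    treatment score, descending; ties broken lexicographically."""
    if TREATMENT_THEME not in model.relation_index:
        raise KeyError(f"theme {TREATMENT_THEME!r} absent from model")
    excluded = exclude.pairs if exclude is not None else set()
    pairs = [
        (d, z) for d in drugs for z in diseases if (d, z) not in excluded
    ]
    if not pairs:
        return []
    H = np.array([model.entity_index[d] for d, _ in pairs], dtype=np.intp)
    T = np.array([model.entity_index[z] for _, z in pairs], dtype=np.intp)
    R = np.full(len(pairs), model.relation_index[TREATMENT_THEME], dtype=np.intp)
    scores = model.test_score_batch(H, R, T)
    order = sorted(range(len(pairs)), key=lambda i: (-scores[i], pairs[i]))
    return [
        RankedCandidate(drug=pairs[i][0], disease=pairs[i][1], score=float(scores[i]), rank=k + 1)
        for k, i in enumerate(order)
    ]


def baseline_treatment_support(graph: KnowledgeGraph, drug: str, disease: str) -> float:
    """The no-embedding baseline: the stored support of the (drug, "T",
    disease) edge, or 0 when the pair has no treatment edge."""
    best = 0.0
    for t in graph.triples:
        if t.theme == TREATMENT_THEME and {t.head, t.tail} == {drug, disease}:
            best = max(best, t.support)
    return best


@dataclass
class EvalResult:
    auroc: float
    aupr: float
    roc_points: pd.DataFrame      # columns fpr, tpr, threshold
    pr_points: pd.DataFrame       # columns recall, precision, threshold
    n_pos: int
    n_neg: int
    seed: int = 0


def evaluate_gold_standard(
    scores_pos: list[float] | np.ndarray,
    scores_neg: list[float] | np.ndarray,
    seed: int = 0,
) -> EvalResult:
    """ROC and PR analysis of positive vs negative scores.

    AUROC is the trapezoidal area of the full ROC curve, identical to the
    Mann-Whitney probability of concordance with half credit for ties; AUPR
    uses step-wise interpolation (average precision).
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    y = np.concatenate([np.ones(scores_pos.size), np.zeros(scores_neg.size)])
    s = np.concatenate([scores_pos, scores_neg])
    fpr, tpr, roc_thr = metrics.roc_curve(y, s, drop_intermediate=False)
    auroc = float(metrics.auc(fpr, tpr))
    precision, recall, pr_thr = metrics.precision_recall_curve(y, s)
    aupr = float(metrics.average_precision_score(y, s))
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr})
    pr_points = pd.DataFrame(
        {
            "recall": recall,
            "precision": precision,
            "threshold": np.append(pr_thr, np.nan),
        }
    )
    return EvalResult(
        auroc=auroc,
        aupr=aupr,
        roc_points=roc_points,
        pr_points=pr_points,
        n_pos=int(scores_pos.size),
        n_neg=int(scores_neg.size),
        seed=seed,
    )


def sample_negative_pairs(
    gold: GoldStandardIndications,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Draw n distinct (drug, disease) pairs uniformly from the gold-standard
    drug and disease universes, excluding known indications."""
    if not gold.pairs:
        raise ValueError("gold standard is empty")
    drugs, diseases = gold.drugs, gold.diseases
    n_valid = len(drugs) * len(diseases) - sum(
        1 for d, z in gold.pairs if d in set(drugs) and z in set(diseases)
    )
    if n > n_valid:
        raise ValueError(f"only {n_valid} valid negative pairs exist; {n} requested")
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    while len(out) < n:
        pair = (
            drugs[int(rng.integers(len(drugs)))],
            diseases[int(rng.integers(len(diseases)))],
        )
        if pair in gold.pairs or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    return out


@dataclass
class ThemeSimilarity:
    """Pairwise cosine similarity of theme embeddings with a hierarchical
    clustering of the themes (distance = 1 - cosine)."""

    matrix: pd.DataFrame            # m x m, symmetric, unit diagonal
    order: list[str]                # theme codes in dendrogram leaf order
    linkage: str
    linkage_matrix: np.ndarray = field(repr=False, default=None)

    def clusters(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return {code: int(lab) for code, lab in zip(self.matrix.index, labels)}


def theme_similarity(model: EmbeddingModel, linkage: str = "average") -> ThemeSimilarity:
    """Cosine-similarity matrix of all relation embeddings, agglomeratively
    clustered on 1 - cosine."""
    codes = model.relation_codes
    if len(codes) < 2:
        raise ValueError("need at least two themes")
    norms = np.linalg.norm(model.R, axis=1)
    for code, nrm in zip(codes, norms):
        if nrm == 0:
            raise ValueError(f"theme {code!r} has a zero-norm embedding")
    U = model.R / norms[:, None]
    cos = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(cos, 1.0)
    dist = 1.0 - cos
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    leaf_order = [codes[i] for i in hierarchy.leaves_list(Z)]
    matrix = pd.DataFrame(cos, index=codes, columns=codes)
    return ThemeSimilarity(matrix=matrix, order=leaf_order, linkage=linkage, linkage_matrix=Z)


def per_theme_precision_at_recall(
    model: EmbeddingModel,
    pairs: list[tuple[str, str]],
    labels: list[bool] | np.ndarray,
    recall_levels: list[float],
    bounded: bool = False,
) -> pd.DataFrame:
    """Precision of each theme's ranking of the given pairs, reported at the
    first rank reaching each recall level.

    Each theme scores every pair with its own relation vector (unbounded
    test score by default, clamped confidence with ``bounded=True``).
    Cuts are made at score thresholds, so tied pairs enter together (with
    constant scores the precision at recall 1 is therefore the label
    prevalence).  Unreachable recall levels are reported as NaN.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 1:
        raise ValueError("need at least one positive label")
    if len(pairs) != labels.size:
        raise ValueError("pairs and labels differ in length")
    H = np.array([model.entity_index[d] for d, _ in pairs], dtype=np.intp)
    T = np.array([model.entity_index[z] for _, z in pairs], dtype=np.intp)
    n_pos = int(labels.sum())
    table = {}
    for code in model.relation_codes:
        R = np.full(len(pairs), model.relation_index[code], dtype=np.intp)
        scores = (
            model.confidence_batch(H, R, T) if bounded else model.test_score_batch(H, R, T)
        )
        order = np.argsort(-scores, kind="stable")
        sorted_scores = scores[order]
        tp = np.cumsum(labels[order])
        ranks = np.arange(1, len(pairs) + 1)
        # cut only where the score strictly drops (ties enter together)
        boundary = np.ones(len(pairs), dtype=bool)
        boundary[:-1] = sorted_scores[:-1] > sorted_scores[1:]
        recall = (tp / n_pos)[boundary]
        precision = (tp / ranks)[boundary]
        row = []
        for level in recall_levels:
            hit = np.nonzero(recall >= level - 1e-12)[0]
            row.append(float(precision[hit[0]]) if hit.size else np.nan)
        table[code] = row
    return pd.DataFrame.from_dict(
        table, orient="index", columns=[f"recall={lv:g}" for lv in recall_levels]
    )
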