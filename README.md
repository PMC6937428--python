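# ukge — uncertain knowledge-graph embeddings for drug repurposing

`ukge` learns confidence-aware embeddings of drugs, diseases, genes and
semantic relationship themes from a *support-scored* heterogeneous
knowledge graph — the kind produced by literature mining, where every edge
carries a continuous confidence in [0, 1] rather than a binary label — and
uses them to generate, explain, and validate drug-repurposing hypotheses.
It is aimed at computational drug-discovery researchers who have (or can
emulate) a GNBR-style themed edge list and a gold-standard indication
list.

## The model

Every entity and theme gets a d-dimensional vector. A triple
*l = (h, r, t)* has bilinear plausibility

```
g(l) = r · (h ∘ t)          (∘ = element-wise product)
```

mapped to a predicted confidence by a learned bounded rectifier

```
f(l) = φ(g(l)),   φ(x) = min(max(w·x + b, 0), 1)
```

and fitted by minimising the squared error between predictions and
observed literature supports s_l, with one tail-corrupted negative triple
(assumed support 0) per observed triple:

```
J = Σ_{l∈L+} |f(l) − s_l|² + Σ_{l∈L−} |f(l)|²
```

Optimisation is minibatch Adam (β₁ = 0.9, β₂ = 0.99) with validation-MSE
early stopping and a learning-rate grid {0.001, 0.005, 0.01}. At test time
the clamp is removed (score = w·g(l) + b) so candidate rankings are
tie-free. Treatment hypotheses are the top-scoring unobserved
(drug, "T", disease) pairs.

Around the embedding model the package provides:

- **graph handling** — typed entities, themed multi-edges, the 32-code
  GNBR-style theme vocabulary, largest-connected-component and
  repurposing-specific filtering, ablation submodels, stratified
  train/validation/test splits (60/20/20 for indication-containing
  triples, 90/5/5 for the rest);
- **evaluation** — ROC/PR against gold-standard indications with sampled
  negative pairs, theme-embedding cosine similarity with hierarchical
  clustering, per-theme precision at recall;
- **explanation** — all simple paths of ≤ 4 nodes between a drug and a
  disease, each edge reduced to its best-supported theme, ranked by
  minimum support, and classified into metapath motifs (DzG-, DzDr-,
  GG-mediated);
- **proximity validation** — median cosine similarity between drug-target
  and disease-gene sets in a protein-interaction embedding, with an
  empirical permutation p-value and Bonferroni correction;
- **synthetic data** — a generator that plants a bilinear ground truth
  with known treatment pairs, so the whole pipeline is testable without
  any external downloads.

## Worked example

`examples/01_train_embeddings.py` generates the default synthetic graph
(20 drugs, 20 diseases, 50 genes, latent dimension 8), splits it, tunes
the learning rate and trains an 8-dimensional model:

```
graph: 90 entities, 2976 triples, 30 planted treatment pairs
split: 2668 train / 154 val / 154 test
tuned learning rate: 0.01
trained for 392 epochs; held-out support MSE = 0.0473
```

The held-out MSE says the model predicts the supports of unseen edges to
within ~0.2 on average — close to the generator's noise floor.
`examples/02_rank_repurposing_candidates.py` then evaluates the planted
indications against recombined negatives and ranks novel candidates:

```
gold-standard evaluation: AUROC=0.976 AUPR=0.979 (30 positives vs 24 negatives)
top 5 novel treatment hypotheses (drug, disease, score):
   1. drug004 -> disease018   0.859
   2. drug019 -> disease004   0.856
   ...
```

`examples/03_explain_prediction.py` reproduces the explanation-mining
worked example — why might acetazolamide (a glaucoma drug) be linked to
amyotrophic lateral sclerosis?

```
score=0.904 motif=DzG: (acetazolamide) [T 0.937] - (glaucoma) [U 0.904] - (OPTN) [U 0.906] - (ALS)
potential mediators (interior genes of top paths): ['OPTN']
```

The path score 0.904 is the minimum best-theme support along the chain:
ACZ treats glaucoma, which shares a causal OPTN mutation with ALS.
`examples/04_theme_analysis.py` and `examples/05_proximity_validation.py`
cover the theme-similarity/precision analyses and the permutation-based
network-proximity test.

A thin CLI mirrors the library (`ukge simulate|train|evaluate|predict|
explain|proximity`); run `ukge --help` for the options.

## Layout

```
src/ukge/        kg.py (data model, I/O, filtering, splits) · themes.py
                 (GNBR-style vocabulary) · synth.py (generators) ·
                 model.py (embedding + training) · evaluate.py ·
                 paths.py (explanations) · proximity.py · cli.py
examples/        one short narrative script per capability
docs/methods.md  model, assumptions, parameter choices, limitations
tests/           pytest suite incl. acceptance checks
```
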