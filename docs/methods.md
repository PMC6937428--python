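# Methods

## The uncertain knowledge-graph embedding model

Literature-mined biomedical graphs attach a continuous support score
s ∈ [0, 1] to each themed edge — the strength of textual evidence that the
relationship holds. Rather than thresholding these scores into binary
edges, the model regresses a predicted confidence onto them. Each entity
(drug, disease, gene) and each semantic theme is a vector in **R**^d; a
triple l = (h, r, t) has bilinear plausibility g(l) = r · (h ∘ t) (a
DistMult-style score, symmetric in head and tail), mapped into [0, 1] by a
learned bounded rectifier φ(x) = min(max(wx + b, 0), 1) with *global*
scalars w and b shared across all themes. The objective is the sum of
squared errors between f(l) = φ(g(l)) and the observed supports over all
graph triples, plus |f(l)|² over an equal number of tail-corrupted
negative triples whose support is assumed to be 0. The assumption behind
negative sampling — that a randomly recombined triple is almost surely
unsupported — holds in literature graphs because related pairs are a
vanishing fraction of all pairs; the synthetic generator is built to
preserve this property (below).

At test time the clamp is removed: candidates are ranked by w·g(l) + b,
which is strictly monotone in g for w > 0 and therefore tie-free for
distinct plausibilities. Treatment hypotheses are top-ranked unobserved
(drug, "T", disease) pairs.

### Training

Minibatch Adam (β₁ = 0.9, β₂ = 0.99) on the squared-error objective;
defaults d = 128, 100 epochs, batch size 1024, matching the reference
setting for a literature-scale graph (the desk-scale runs in the tests
and examples use d = 8 and smaller batches to match the synthetic graph's
latent dimension). One fresh corrupted negative per positive is drawn each
epoch (a flag freezes them instead); corrupted tails are drawn uniformly
from all entities excluding the original tail, irrespective of type (a
flag restricts corruption to the tail's type, and another filters
corruptions that collide with observed positives). Validation mean squared
error — bounded confidence on held-out positives, by default without
negatives — is evaluated every epoch and drives early stopping with
patience 5 (desk-scale runs use longer patience since their epochs are
cheap); the parameters at the best validation MSE are returned. The
learning rate is tuned over {0.001, 0.005, 0.01} by validation MSE, ties
toward the smaller rate.

Two numerical choices matter:

- **Initialisation**: entity and relation vectors uniform in
  [−0.5/√d, +0.5/√d]; w = 1, b = 0. This keeps initial plausibilities
  near zero, inside the identity region of φ.
- **Leaky rectifier subgradient** (`TrainConfig.grad_leak`, default 0.01):
  φ has zero gradient outside (0, 1), so a positive triple whose
  prediction is pushed below zero early in training would otherwise be
  permanently stuck (the residual is large but the exact subgradient
  vanishes). During optimisation only, the rectifier's gradient is given
  a small slope outside the bounds. The loss value, the reported
  gradients of the objective (`loss_gradients`), and all scoring use the
  exact clamped form; the leak is purely an optimisation device, and
  setting it to 0 recovers plain subgradient descent.

Divergence (non-finite loss or parameters) raises an error naming the
epoch. Training is deterministic given the seed; all randomness flows
through one `numpy` generator.

Gradients are computed analytically (dense NumPy, scatter-added per
batch); they are verified against central finite differences of the exact
clamped objective in the test suite.

## Graph handling

Connectivity is undirected and theme-agnostic throughout: the largest
connected component ties are broken toward the component containing the
lexicographically smallest entity id. The repurposing filter keeps gene
nodes, designated high-priority disease nodes, and drug/disease nodes
appearing in a known indication, then takes the largest connected
component. Ablation submodels: `treatment_only_drdz` (drop non-"T"
drug-disease triples), `no_genes` (drop gene-touching triples, then the
component of the bipartite remainder), `treatment_edges_only` (the
no-embedding baseline scored directly by stored support).

Splits stratify by whether a triple's unordered endpoint pair is a known
indication (any theme, not only "T"): indication-containing triples split
60/20/20, all others 90/5/5, with floor allocation and the remainder to
the training fold. By default stratification is per triple; a flag groups
all triples of one indication pair into the same fold.

## The synthetic generator

The generator exists so that every downstream stage — training,
evaluation, explanation, proximity — can be exercised against a known
ground truth. It plants exactly the structure the model assumes: latent
vectors z_i for entities and r_c for themes, and supports
s = clamp(w_true·(r_c · (z_h ∘ z_t)) + b_true + ε, 0, 1) with
ε ~ N(0, noise_sd²), noise_sd = 0.05 by default.

Design choices, and the features of real data they emulate:

- **Community structure.** Entity latents sit near one of `n_clusters`
  (default 5) type-specific Gaussian centres with individual deviation
  `cluster_sd` (default 0.3). Biomedical graphs are modular — drug
  classes, disease families, gene pathways — and this redundancy is what
  makes latent structure learnable from a desk-scale number of edges;
  with i.i.d. latents the bilinear model is unidentifiable at these sizes
  and nothing generalises.
- **Sparse relatedness.** (w_true, b_true) are calibrated per graph so the
  80th-percentile candidate pair maps to support 0 (the clamp makes ~80%
  of random pairs exactly unsupported) and the weakest planted treatment
  pair maps to 0.92. A random corrupted triple therefore has support near
  0, as negative sampling assumes.
- **Support-weighted observation.** Each candidate (pair, theme) edge is
  included with probability proportional to its noise-free support,
  normalised so the expected edge count per category is
  edge_density × pair count (default density 0.8 at desk scale). Related
  pairs are the ones the literature writes about; because all themes of a
  pair share the same h ∘ t interaction, strongly related pairs acquire
  several correlated themed edges — the cross-theme redundancy that the
  embedding model exploits.
- **Planted indications.** The `n_planted_indications` (default 30)
  drug-disease pairs with the highest noise-free treatment score are the
  gold standard, forced into the edge set; their treatment edges are
  stored noise-free, which guarantees support ≥ 0.9 by the calibration.
- Three themes per category (drawn from the head of the 32-code default
  vocabulary, always including "T") and no drug-drug or disease-disease
  edges, matching the four-category schema.

What the generator does **not** emulate: literature citation dynamics,
sentence-level provenance, hub-dominated degree distributions, entity
ambiguity, or systematic biases of text mining (e.g. the cancer literature
bias). Passing tests on synthetic graphs therefore demonstrate that the
implementation recovers the model's own assumed structure at desk scale —
not that the method's headline numbers on a real literature graph are
reproduced here, which would require the full external datasets.

The proximity fixture draws a Gaussian protein embedding; under
`effect = 0` both gene sets are drawn with replacement from all proteins,
exchangeable with the permutation null (p-values are uniform by
construction); under `effect > 0` both sets are shifted along a common
latent direction by `effect` units, raising their median cosine.

## Evaluation

Gold-standard evaluation scores known indications (positives) and
recombined drug-disease pairs sampled uniformly from the gold-standard
universes (negatives, excluding known indications and duplicates). AUROC
is the trapezoidal area of the full ROC curve — identical to Mann-Whitney
concordance with half-credit ties — and AUPR uses step-wise interpolation
(average precision), avoiding the optimism of linear PR interpolation.
Theme similarity is the cosine matrix of relation vectors with average-
linkage agglomerative clustering on 1 − cosine. Per-theme
precision-at-recall scores every pair under each theme's relation vector
(unbounded scores by default; a flag uses bounded confidences) and reports
precision at the first score threshold reaching each recall level, with
tied scores entering together — hence with constant scores the precision
at recall 1 is the label prevalence; unreachable levels are NaN, not an
error.

## Explanation mining

All simple undirected paths with between 2 and 4 nodes (≤ 3 edges)
between a drug and a disease are enumerated (a configurable cap, default
10⁶ paths, guards against hub blow-ups); each step is reduced to its
highest-supported theme over all parallel edges in either orientation
(ties alphabetical by code); the path score is the minimum support along
the path — a weakest-link measure — and ranking ties go to shorter paths,
then lexicographic node order. Four-node paths map to motifs by interior
node types after orienting drug→disease: disease-gene (DzG-mediated,
shared genetic mechanism), disease-drug (DzDr-mediated, shared
treatment), gene-gene (GG-mediated, interacting genes). Two-node paths
are "direct"; everything else — including three-node paths, whose shapes
the motif taxonomy deliberately does not cover — is "other". Direct edges
are excluded from motif statistics. Potential mediators are the interior
gene nodes of the ranked paths.

## Proximity validation

The statistic is the median cosine similarity over all |A|×|B| pairs
between a drug-target set and a disease-gene set in a consumed
protein-interaction embedding (e.g. a 128-dimensional node embedding of a
PPI network; computing the embedding is out of scope). Set members absent
from the embedding are dropped; a set empty after intersection yields an
"N/A" result rather than an error, mirroring untestable pairs. The null
draws |A| and |B| proteins with replacement from the whole embedded
proteome (duplicates allowed within a replicate) and recomputes the
median; the p-value uses the add-one estimator (1 + b)/(1 + N), which is
strictly positive, with N = 10,000 replicates by default. Significance
applies a Bonferroni threshold α / m where m counts only testable pairs.
Resampling is uniform — it does not preserve degree or other covariates.

## Problem sizes in the test suite

The acceptance-style checks run at desk scale: the default synthetic
graph (90 entities, ~3,000 triples), d = 8 training with the learning-rate
grid, 100 random instances per brute-force oracle, 200 repetitions at 500
permutations for the calibration study, and 10⁵ random triples for the
clamping contract. These sizes were chosen so the full suite completes in
well under a minute while leaving the statistical checks enough power to
fail loudly when broken.

## Known limitations

- Dense-matrix training: gradients are scatter-added into full embedding
  matrices, appropriate up to ~10⁵ entities; a literature-scale run would
  want sparse updates or an autodiff backend.
- Edge direction and semantic granularity are ignored, as in the
  underlying model; contraindication-style errors (a drug linked to a
  disease through a shared gene it does not target) are detectable only
  through the explanation paths, not prevented.
- The bounded rectifier loses gradient information for saturated triples;
  the leaky subgradient mitigates but does not remove this.
- Ranking quality near the decision boundary depends on the margin
  between true indications and near-miss recombinations; on synthetic
  graphs this margin is controlled by the planting calibration, on real
  data by the curation quality of the gold standard.
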