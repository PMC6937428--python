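"""Rank novel drug-disease treatment candidates and evaluate against the
planted gold standard.

Candidates are scored with the unbounded test-time score w*g(l)+b under the
treatment theme "T"; known indications are excluded so the ranking contains
only novel hypotheses.  Evaluation follows the standard protocol: planted
indications as positives, recombined drug-disease pairs as negatives.
"""

import numpy as np

from ukge import (
    SyntheticConfig, generate_kg, split_triples,
    evaluate_gold_standard, sample_negative_pairs, score_treatment_candidates,
    test_score,
)
from ukge.kg import EntityType
from ukge.model import TrainConfig, train

graph, truth = generate_kg(SyntheticConfig(seed=0))
split = split_triples(graph, truth.planted_pairs, seed=0)
model, _ = train(split, TrainConfig(d=8, epochs=800, batch_size=256,
                                    learning_rate=0.01, early_stop_patience=150,
                                    seed=0), graph=graph)

gold = truth.planted_pairs
rng = np.random.default_rng(0)
n_valid = len(gold.drugs) * len(gold.diseases) - len(gold.pairs)
negatives = sample_negative_pairs(gold, min(len(gold), n_valid), rng)
pos = [test_score(model, (d, "T", z)) for d, z in sorted(gold.pairs)]
neg = [test_score(model, (d, "T", z)) for d, z in negatives]
result = evaluate_gold_standard(pos, neg)
print(f"gold-standard evaluation: AUROC={result.auroc:.3f} AUPR={result.aupr:.3f} "
      f"({result.n_pos} positives vs {result.n_neg} negatives)")

drugs = graph.entities_of_type(EntityType.DRUG)
diseases = graph.entities_of_type(EntityType.DISEASE)
ranked = score_treatment_candidates(model, drugs, diseases, exclude=gold)
print("top 5 novel treatment hypotheses (drug, disease, score):")
for c in ranked[:5]:
    print(f"  {c.rank:2d}. {c.drug} -> {c.disease}   {c.score:.3f}")
print("(higher scores mean stronger predicted treatment confidence; these "
      "unobserved pairs are the repurposing hypotheses)")
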