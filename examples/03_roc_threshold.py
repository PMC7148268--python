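"""Evaluate the consistency score as a diagnostic with ROC analysis.

Simulates a default labeled cohort (28 synesthetes, 57 controls; five-taste
scheme), scores everyone, and finds the maximum-efficiency threshold — the
cutoff classifying the largest share of participants in line with their
self-report.
"""

from lgsyn import (
    LabeledScore,
    SimulationConfig,
    classify,
    roc_analysis,
    simulate_cohort,
    taste_consistency,
)

cohort = simulate_cohort(SimulationConfig(scheme="five_taste", seed=1))
scores = [
    LabeledScore(rec.participant_id, taste_consistency(rec).mean_percent, status)
    for rec, status in cohort
]

result = roc_analysis(scores)
opt = result.optimal_point
print(f"participants: {len(scores)}  (28 synesthetes vs 57 controls)")
print(f"AUC = {result.auc:.3f}  (.5 = guessing, 1 = perfect separation)")
print(f"max-efficiency cutoff = {opt.cutoff:.2f}%")
print(f"  sensitivity {opt.sensitivity:.2%}  specificity {opt.specificity:.2%}"
      f"  efficiency {opt.efficiency:.2%}")

newcomer = 31.4  # a new participant's consistency score
print(f"\nscore {newcomer}% at this cutoff -> {classify(newcomer, opt.cutoff)}")
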