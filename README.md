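# lgsyn

Automated consistency-test scoring and ROC-based threshold evaluation for
screening **lexical–gustatory (LG) synesthesia** — the rare condition in
which words automatically trigger specific flavor experiences ("audience"
tasting of tinned peas) or intrusive food thoughts.

## The problem

LG synesthesia cannot be diagnosed by self-report alone: nonsynesthetes
struggle to distinguish ordinary word–food associations from synesthetic
ones, producing high acquiescence bias. The established objective paradigm
is the *test of consistency*: elicit a word–flavor association for each word
in a list, elicit it again later, and measure how reliably the pairings are
reproduced. Genuine synesthetes are far more consistent than controls even
when the retest follows within the same session. `lgsyn` implements the
scoring, self-report classification, and diagnostic-threshold machinery for
the two automated variants of this test, plus a seeded cohort simulator so
the whole pipeline is testable without participant data.

## Scores

**Category scheme.** Each word is answered twice by picking a food from a
hierarchical palette (11 superordinate categories, 87 subordinate foods,
packaged in `lgsyn/data/palette.yaml`) plus an intensity on a 1–100 slider,
or a no-taste button. Per word: 2 points for an exact match across
presentations (same category and food), 1 for a partial match (same
category only), 0 otherwise. Words answered no-taste in *both*
presentations are excluded from numerator and denominator, so with
`n` words receiving at least one food,

```
consistency % = 100 · Σ points / (2 n)
```

A naive counterfactual variant (`naive_category_consistency`) credits
double no-taste words with 2 points each, documenting why the exclusion
rule exists. Intensity consistency is the Pearson correlation of the
two presentations' ratings (0 substituted on one-sided no-taste words,
double no-taste words dropped).

**Five-taste scheme.** Each word's associated food is described as a
compositional pie-chart profile over sweet, sour, salty, bitter and umami
(summing to 100%). Per taste *t*, consistency is the coefficient of
determination R²ₜ of the simple regression between the presentation-1 and
presentation-2 percentages across words (equal to the squared Pearson
correlation, hence direction-invariant). Tastes assigned on ≤ 10% of words
(≤ 3 of 30) are excluded as unreliable; the score is

```
score % = 100 · mean{ R²ₜ : t included }
```

**Diagnostics.** Treating self-report (classified from the questionnaire
flow: *yes* + flavors-in-mouth → projector synesthete, *yes* +
thoughts-in-mind → associator, anything else → nonsynesthete) as ground
truth, `roc_analysis` computes sensitivity `P(score > c | synesthete)`,
specificity `P(score ≤ c | nonsynesthete)` and efficiency `(TP+TN)/N` at
every observed cutoff `c`, the rank-based AUC (ties ½), and the
maximum-efficiency cutoff. Packaged recommended cutoffs: 75.00%
(category), 26.06% (five-taste).

## Worked example

```python
from lgsyn import category_consistency, naive_category_consistency
from lgsyn.fixtures import worked_example_record

rec = worked_example_record()   # 4 exact, 1 partial, 5 mismatch, 20 double no-taste
print(category_consistency(rec))
print(naive_category_consistency(rec))
```

prints

```
9/20 points = 45.00%
49/60 points = 81.67%
```

Ten words received at least one food, so 20 points were available; 4 exact
matches (8) + 1 partial (1) = 9 points → 45.00%, a poor score. The naive
variant would have credited the 20 consistently-silent words too (49/60),
which is why the exclusion rule exists. See `examples/` for the five-taste
score, the ROC threshold search and the CSV pipeline; the same flows are
available on the command line:

```
lgsyn simulate --scheme five_taste --seed 7 --out responses.csv
lgsyn score-tastes responses.csv --labels responses_labels.csv --out results.csv
lgsyn demo
```

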