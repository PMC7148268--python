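# Methods

## Scoring model

### Category scheme

A participant record holds, for each word `w` in the list, a pair of
responses `(r₁(w), r₂(w))` from the two blocked presentations. Under the
category scheme each response is either a `(category, food)` pair from the
hierarchical palette plus an intensity in [1, 100], or a no-taste flag.
Per-word points:

| pair | points |
|---|---|
| same category, same food | 2 |
| same category, different food | 1 |
| different categories | 0 |
| exactly one no-taste | 0 (word still counts) |
| both no-taste | excluded (word does not count) |

The consistency score is `100 · Σ points / (2 n)`, with `n` the number of
words given at least one food. The exclusion of double no-taste words is
essential: without it a respondent who declines most words scores as highly
consistent (the packaged worked example moves from 45.00% to 81.67%). The
naive variant is retained, clearly labeled, for exactly this demonstration
and for testing; it is not a diagnostic score.

One-sided no-taste words intentionally stay in the denominator with 0
points: a food was provided for them, and failing to reproduce it is
inconsistency, not missing data.

Intensity consistency is the Pearson correlation between the two
presentations' ratings over the same word set (0 substituted on the
no-taste side of one-sided words; double no-taste words dropped). Pearson
was chosen as the default reading of "correlation coefficient" on interval
slider data; Spearman would be a defensible alternative and the choice is
isolated in one function.

### Five-taste scheme

Responses are compositional profiles `p(w) ∈ Δ⁴ · 100` over
(sweet, sour, salty, bitter, umami), validated to sum to 100 within 1e-6.
`normalize_profile` converts absolute per-taste ratings to this composition
by scaling with `100/Σ`; an all-zero input has no composition and is an
error.

Per taste `t`, `R²ₜ` is the coefficient of determination of the simple
linear regression between `{p₁ₜ(w)}` and `{p₂ₜ(w)}` across words. For
simple regression `R² = r²` (squared Pearson), which is symmetric in the
two presentations — so the otherwise ambiguous regression direction is
immaterial, and this symmetry is asserted as a property test. `R²ₜ` is
undefined when either vector is constant; undefined tastes are dropped
from the average and reported.

Data-quality rules, in order:

1. Double no-taste words are dropped; one-sided no-taste words have the
   missing side replaced by the all-zero profile. (The wholesale exclusion
   of double no-taste words mirrors the category scheme's rationale —
   consistent silence must not earn consistency.)
2. A taste enters the average only if it was *assigned* — nonzero in at
   least one presentation — on strictly more than 10% of the record's
   words (> 3 of 30 for the canonical instrument). "At least one
   presentation" is the most inclusive reading of an underspecified rule;
   the threshold generalizes as `count > 0.10 · n_words`, which reproduces
   the canonical "> 3 of 30" exactly. `apply_sparse_rule=False` scores
   without step 2, supporting the audit that the rule does not
   systematically advantage either group.

The score is `100 · mean(R²ₜ)` over included tastes. An empty inclusion
set raises an undefined-score signal — never a silent 0, since 0 is a
legitimate (very inconsistent) score and absence is not.

## Self-report classification

The questionnaire flow maps to three labels: an initial "yes" sustained as
flavors-in-the-mouth → projector synesthete; sustained as
thoughts-in-the-mind → associator synesthete; an initial "no", or a "yes"
retracted as a mistake → nonsynesthete. The follow-up `not_applicable` is
valid exactly when the initial answer is "no". For diagnostics both
synesthete sub-labels collapse to one positive class; no score depends on
the sub-label.

## ROC evaluation

Candidate cutoffs are the distinct observed scores plus one sentinel below
the minimum (everyone classified positive), reproducing a score continuum
at the data's resolution rather than a fixed grid. Classification is
strict: `score > cutoff → synesthete`. Per cutoff we report sensitivity,
specificity, efficiency `(TP+TN)/N`, and Youden's J as a convenience
column; the recommended threshold is the efficiency maximizer, ties broken
toward higher sensitivity and then the lower cutoff. Efficiency, not
Youden's J, selects the headline cutoff.

AUC uses the Mann–Whitney rank formulation with average ranks, i.e. tied
pairs get ½ credit; this equals the trapezoidal area under the
strict-threshold ROC curve, an identity verified to 1e-12 against an
all-pairs counting oracle and an independent library implementation in the
tests. No confidence intervals beyond this point estimate are attempted:
the standard-error conventions of statistics packages vary and validating
them would require the original cohort data.

## Cohort simulator

No distributional model of real responders exists, so the generator is an
explicit invention; it emulates only the structure the scorers consume.

Category scheme, per word: a latent `(category, food)` is drawn uniformly
over the 87 palette foods and a latent intensity from
`N(intensity_mu, intensity_sd)`. Presentation 1 emits the latent
association with probability `p_taste`, else no-taste. Presentation 2
(independently no-taste with `1 − p_taste`) repeats the food exactly with
probability `p_exact`, stays in-category with a different food with
`p_partial`, and otherwise draws a fresh uniform food. Each emitted
intensity adds independent `N(0, intensity_noise_sd)` noise and clamps to
[1, 100].

Five-taste scheme, per word: a latent composition is drawn from a
symmetric Dirichlet(`profile_sparsity`) (default 0.5, favoring profiles
dominated by one or two tastes, as food flavors are); each presentation
re-draws from Dirichlet(`concentration · latent + 0.01`) scaled to 100.
The 0.01 floor keeps zero components feasible and mirrors the pie-chart
widget, whose segments start at ≥ 1.

The RNG is numpy's PCG64 (`default_rng`), named in the config metadata; a
seed fully determines a cohort. Default cohort sizes are 28 synesthetes
(17 projectors / 11 associators, matching the recruitment split at that
size; any other size splits evenly — cosmetic, since no score uses the
sub-label) versus 57 controls, 30 words.

**Calibration.** Default parameters live in `src/lgsyn/data/defaults.yaml`
and were fixed by a Monte-Carlo calibration run targeting the published
group medians of the two instruments (category: ≈ 85.9 synesthete vs.
≈ 45.0 control; five-taste: ≈ 67.8 vs. ≈ 13.3), with a declared tolerance
of ±4 percentage points on cohort medians. Defaults reproduce:
synesthetes `p_taste 0.95, p_exact 0.92, p_partial 0.04` vs. controls
`p_exact 0.40, p_partial 0.13` (category); `concentration 30` vs. `0.62`
(five-taste). Calibration targets medians, not AUCs, because medians are
the directly printed score summaries. The simulated groups are
homogeneous, so simulated cohorts separate more cleanly (AUC ≈ 1) than
heterogeneous human cohorts; passing Monte-Carlo tests therefore
demonstrates correctness of the scoring/ROC machinery and the direction
and rough size of group differences, not realistic human overlap, tails,
or word-level structure (childhood-diet or phonological effects are out of
scope). A further known gap: Dirichlet draws are continuous, so simulated
pie-chart profiles never contain exact zeros and the sparse-taste rule
essentially never fires on simulated cohorts; the neutrality audit of that
rule therefore uses purpose-built sparse responders in the test suite.

## Numerical choices and degenerate inputs

- Undefined results (all-double-no-taste records, < 2 correlation pairs,
  zero-variance vectors, empty R² inclusion sets) raise
  `UndefinedScoreError`; the pipeline converts them to NaN rows plus a
  structured `undefined_score` exclusion event. They are never coerced
  to 0.
- Every dropped word (`double_no_taste`), taste (`sparse_taste`,
  `undefined_r2`) and participant (`undefined_score`) is reported exactly
  once as a machine-readable exclusion event and mirrored to the `lgsyn`
  logger.
- Scores are kept at full precision internally and rendered to 2 decimals
  at the presentation layer (`45.00%`).
- Food identity is the `(category, food)` pair, case-sensitive after
  whitespace normalization; the palette loader enforces uniqueness and
  non-emptiness and round-trips YAML/JSON byte-stably.
- CSV interchange uses `float_precision="round_trip"` parsing so
  write→read preserves scores and intensities exactly.
- The packaged word list is a synthetic stand-in (the instrument's
  published word lists are not redistributed); all scorers are word-list
  agnostic for any n ≥ 1, with the 10% sparse-taste rule scaling
  accordingly.

## Problem sizes used in tests

Property tests run at n ≤ 30 words and cohorts of ≤ 85; the Monte-Carlo
acceptance checks use 500 default cohorts for the separation claim and 200
for the null (shared-parameter) claim, sizes at which the whole suite
completes in about a minute on one core while leaving the Monte-Carlo
standard errors far below the tested margins.
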