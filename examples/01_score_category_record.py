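"""Score one participant under the category (food palette) scheme.

Builds the canonical worked-example record — 4 exact matches, 1 partial
match, 5 category mismatches and 20 words answered no-taste in both
presentations — and scores it with and without the no-taste-exclusion rule.
"""

from lgsyn import category_consistency, mean_intensity, naive_category_consistency
from lgsyn.fixtures import worked_example_record

record = worked_example_record()

strict = category_consistency(record)
naive = naive_category_consistency(record)

print(f"words scored (>=1 food given): {strict.n_words_scored}")
print(f"double no-taste words dropped: {strict.n_double_no_taste}")
print(f"consistency (exclusion rule):  {strict}")
print(f"naive counterfactual:          {naive}")
print(f"mean intensity, presentation 1: {mean_intensity(record, 1):.1f}")

# The exclusion rule is the difference between a poor scorer (45.00%) and an
# apparently excellent one (81.67%): consistent silence is not consistency.
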