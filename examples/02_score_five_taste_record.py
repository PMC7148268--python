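"""Score one participant under the five-taste (pie chart) scheme.

Shows the normalization from absolute ratings to a compositional profile,
then scores a small record: per-taste test-retest R² and their mean as a
percentage.
"""

from lgsyn import normalize_profile, taste_consistency
from lgsyn.fixtures import toy_five_taste_record

# Absolute Likert-style ratings (very sweet AND very sour) become relative
# contributions on the pie chart: 50% sweet, 50% sour.
candy = normalize_profile(sweet=80, sour=80, salty=0, bitter=0, umami=0)
print("sour-sweet candy profile:", tuple(round(v, 1) for v in candy.values))

record = toy_five_taste_record()
res = taste_consistency(record)
print(f"\nwords used: {res.n_words_used} "
      f"(dropped {res.n_double_no_taste} double no-taste)")
for taste, r2 in res.per_taste_r2.items():
    note = "included" if taste in res.included_tastes else "excluded"
    print(f"  R^2({taste:6s}) = {r2:.4f}  [{note}]")
print(f"mean consistency: {res.mean_percent:.2f}%")
# Each R^2 says how well presentation-1 percentages for that taste predict
# presentation-2 percentages across words; the mean, as a percent, is the
# participant's five-taste consistency score.
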