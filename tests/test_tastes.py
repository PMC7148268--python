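"""Five-taste scheme: normalization, per-taste R², sparse-taste exclusion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lgsyn import (
    TasteProfile,
    UndefinedScoreError,
    ValidationError,
    normalize_profile,
    taste_consistency,
    taste_r2,
)
from lgsyn.tastes import sparse_taste_threshold
from conftest import make_taste_record, random_profile

# mean percent of the 6-word toy record, frozen from an independent
# ordinary-least-squares oracle computed before implementation
TOY_RECORD_MEAN_PERCENT = 72.81147748793447


class TestNormalize:
    def test_sour_sweet_candy_example(self):
        """Absolute (80, 80, 0, 0, 0) becomes relative 50/50: the pie chart
        records contribution shares, not absolute strengths."""
        p = normalize_profile(80, 80, 0, 0, 0)
        assert p.values == pytest.approx((50, 50, 0, 0, 0))

    def test_already_normalized_unchanged(self):
        assert normalize_profile(100, 0, 0, 0, 0).values == (100, 0, 0, 0, 0)

    def test_all_zero_has_no_composition(self):
        with pytest.raises(ValidationError):
            normalize_profile(0, 0, 0, 0, 0)

    @given(st.lists(st.floats(0, 1000), min_size=5, max_size=5)
           .filter(lambda v: sum(v) > 1e-6))
    def test_output_sums_to_100_and_preserves_ratios(self, vals):
        p = normalize_profile(*vals)
        assert sum(p.values) == pytest.approx(100, abs=1e-6)
        total = sum(vals)
        assert p.values == pytest.approx(tuple(100 * v / total for v in vals))


class TestTasteR2:
    def test_identical_vectors_give_one(self):
        assert taste_r2([10, 40, 50], [10, 40, 50]) == pytest.approx(1.0)

    def test_constant_vector_is_undefined(self):
        assert taste_r2([5, 5, 5], [1, 2, 3]) is None
        assert taste_r2([1, 2, 3], [5, 5, 5]) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            taste_r2([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    def test_equals_squared_pearson_and_symmetric(self, seed):
        """R² of the simple regression = squared Pearson r, so the regression
        direction is immaterial."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, 8)
        y = rng.uniform(0, 100, 8)
        # brute-force least squares, written out
        X = np.column_stack([np.ones(8), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        sse = float(((y - X @ beta) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        expected = 1 - sse / sst
        assert taste_r2(x, y) == pytest.approx(expected, abs=1e-12)
        assert taste_r2(x, y) == pytest.approx(taste_r2(y, x), abs=1e-12)
        assert 0 <= taste_r2(x, y) <= 1


class TestTasteConsistency:
    def test_exact_copy_scores_100(self):
        rng = np.random.default_rng(0)
        profiles = [random_profile(rng) for _ in range(8)]
        rec = make_taste_record([(p, p) for p in profiles])
        assert taste_consistency(rec).mean_percent == pytest.approx(100.0)

    def test_toy_record_matches_frozen_oracle(self, toy_taste_record):
        res = taste_consistency(toy_taste_record)
        assert res.n_words_used == 5          # w6 (double no-taste) dropped
        assert res.n_double_no_taste == 1
        assert res.included_tastes == ("sweet", "sour", "salty", "bitter", "umami")
        assert res.mean_percent == pytest.approx(TOY_RECORD_MEAN_PERCENT, abs=1e-9)

    def test_sparse_taste_excluded_from_average(self):
        """A taste assigned on too few words is dropped; the mean covers the
        remaining tastes."""
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(30):
            v = rng.dirichlet([1, 1, 1, 1]) * 100
            if i == 0:  # bitter appears on exactly one word (1 <= 3 of 30)
                p = TasteProfile.taste(v[0] / 2, v[1] / 2, v[2] / 2, 50 + v[3] / 2, 0)
                pairs.append((p, p))
            else:
                p1 = TasteProfile.taste(v[0], v[1], v[2], 0, v[3])
                w = rng.dirichlet([1, 1, 1, 1]) * 100
                p2 = TasteProfile.taste(w[0], w[1], w[2], 0, w[3])
                pairs.append((p1, p2))
        res = taste_consistency(make_taste_record(pairs))
        assert "bitter" in res.sparse_tastes
        assert "bitter" not in res.included_tastes
        expected = 100 * np.mean([res.per_taste_r2[t] for t in res.included_tastes])
        assert res.mean_percent == pytest.approx(expected)
        # the audit variant keeps bitter in
        res_all = taste_consistency(make_taste_record(pairs), apply_sparse_rule=False)
        assert "bitter" in res_all.included_tastes

    def test_threshold_reproduces_canonical_rule(self):
        # canonical 30-word instrument: included iff assigned on > 3 words
        assert not 3 > sparse_taste_threshold(30)
        assert 4 > sparse_taste_threshold(30)

    def test_double_no_taste_only_record_is_undefined(self):
        nt = TasteProfile.no_taste()
        with pytest.raises(UndefinedScoreError):
            taste_consistency(make_taste_record([(nt, nt)] * 4))

    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_word_relabeling_and_presentation_swap(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [(random_profile(rng), random_profile(rng)) for _ in range(8)]
        base = taste_consistency(make_taste_record(pairs)).mean_percent
        perm = rng.permutation(len(pairs))
        shuffled = taste_consistency(
            make_taste_record([pairs[i] for i in perm])).mean_percent
        swapped = taste_consistency(
            make_taste_record([(b, a) for a, b in pairs])).mean_percent
        assert shuffled == pytest.approx(base, abs=1e-9)
        assert swapped == pytest.approx(base, abs=1e-9)
        assert 0 <= base <= 100

    def test_sparse_rule_is_neutral_on_average(self):
        """Dropping rarely-assigned tastes changes mean scores by a small,
        non-directional amount: it is a reliability fix, not a bias.

        Uses purpose-built sparse responders (each word's profile supported
        on two tastes, bitter rarely used), since pie-chart users leave most
        segments at exactly zero."""
        rng = np.random.default_rng(0)
        weights = np.array([0.3, 0.25, 0.25, 0.03, 0.17])  # bitter rare

        def sparse_profile(support, split):
            v = np.zeros(5)
            v[support] = split * 100
            return TasteProfile.taste(*v)

        def sparse_record(pid, fidelity):
            pairs = []
            for _ in range(30):
                support = rng.choice(5, size=2, replace=False, p=weights)
                split = rng.dirichlet([1, 1])
                p1 = sparse_profile(support, split)
                if rng.random() < fidelity:  # same support, jittered split
                    p2 = sparse_profile(support, rng.dirichlet(20 * split + 0.5))
                else:  # a fresh association
                    p2 = sparse_profile(
                        rng.choice(5, size=2, replace=False, p=weights),
                        rng.dirichlet([1, 1]))
                pairs.append((p1, p2))
            return make_taste_record(pairs, pid)

        diffs = []
        for i in range(40):
            rec = sparse_record(f"p{i}", fidelity=0.9 if i % 2 else 0.2)
            with_rule = taste_consistency(rec)
            without = taste_consistency(rec, apply_sparse_rule=False)
            if with_rule.sparse_tastes:  # only affected records inform the audit
                diffs.append(with_rule.mean_percent - without.mean_percent)
        assert len(diffs) >= 10  # the rule fires for many sparse responders
        assert abs(np.mean(diffs)) < 10.0

    def test_one_sided_no_taste_is_zero_substituted(self):
        t = TasteProfile.taste
        nt = TasteProfile.no_taste()
        pairs = [(t(100, 0, 0, 0, 0), t(90, 10, 0, 0, 0)),
                 (t(0, 100, 0, 0, 0), nt),
                 (t(50, 50, 0, 0, 0), t(40, 60, 0, 0, 0))]
        res = taste_consistency(make_taste_record(pairs))
        # sweet vectors: (100, 0, 50) vs (90, 0, 40) -- the no-taste side is 0
        x = np.array([100, 0, 50.0]); y = np.array([90, 0, 40.0])
        r = np.corrcoef(x, y)[0, 1]
        assert res.per_taste_r2["sweet"] == pytest.approx(r * r)
        assert res.n_words_used == 3
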