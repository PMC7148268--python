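"""Category-scheme consistency scoring: point rules, exclusions, intensity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lgsyn import (
    PaletteResponse,
    UndefinedScoreError,
    category_consistency,
    intensity_consistency,
    mean_intensity,
    naive_category_consistency,
    score_trial_pair,
)
from lgsyn.category import EXCLUDED
from conftest import make_category_record, random_category_record

BUTTER = PaletteResponse.taste("Fats", "Butter", 50)
VEGFAT = PaletteResponse.taste("Fats", "Vegetable fat (e.g., margarine)", 50)
TEA = PaletteResponse.taste("Beverages", "Tea", 50)
NT = PaletteResponse.no_taste()


class TestTrialPair:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (BUTTER, BUTTER, 2),      # exact: same category and food
            (BUTTER, VEGFAT, 1),      # partial: same category only
            (BUTTER, TEA, 0),         # different categories
            (BUTTER, NT, 0),          # one-sided no-taste: scored, 0 points
            (NT, BUTTER, 0),
            (NT, NT, EXCLUDED),       # double no-taste: word not scored
        ],
    )
    def test_point_rules(self, r1, r2, expected):
        assert score_trial_pair(r1, r2) is expected if expected is EXCLUDED \
            else score_trial_pair(r1, r2) == expected

    def test_symmetric(self):
        assert score_trial_pair(BUTTER, VEGFAT) == score_trial_pair(VEGFAT, BUTTER)


class TestCategoryConsistency:
    def test_worked_example(self, worked_example):
        """4 exact + 1 partial + 5 mismatch + 20 double no-taste -> 9/20 = 45.00%."""
        res = category_consistency(worked_example)
        assert res.points_awarded == 9
        assert res.points_available == 20
        assert res.n_words_scored == 10
        assert res.n_double_no_taste == 20
        assert res.percent == pytest.approx(45.00, abs=1e-12)
        assert f"{res.percent:.2f}" == "45.00"

    def test_worked_example_naive_counterfactual(self, worked_example):
        """Crediting double no-taste words gives the same record 49/60 points."""
        res = naive_category_consistency(worked_example)
        assert res.points_awarded == 49
        assert res.points_available == 60
        assert f"{res.percent:.2f}" == "81.67"

    def test_all_exact_scores_100(self):
        rec = make_category_record([(BUTTER, BUTTER)] * 30)
        assert category_consistency(rec).percent == 100.0

    def test_three_word_mixture(self):
        # one exact (2), one partial (1), one one-sided no-taste (0 of 2)
        rec = make_category_record([(BUTTER, BUTTER), (BUTTER, VEGFAT), (BUTTER, NT)])
        res = category_consistency(rec)
        assert (res.points_awarded, res.points_available) == (3, 6)
        assert res.percent == pytest.approx(50.0)

    def test_all_double_no_taste_is_undefined_not_zero(self):
        rec = make_category_record([(NT, NT)] * 5)
        with pytest.raises(UndefinedScoreError):
            category_consistency(rec)
        # the naive variant, by contrast, credits everything
        naive = naive_category_consistency(rec)
        assert (naive.points_awarded, naive.points_available) == (10, 10)

    @given(st.integers(0, 2**31 - 1))
    def test_equivalence_without_no_taste(self, seed):
        """With no no-taste responses the two scoring variants coincide."""
        rec = random_category_record(np.random.default_rng(seed), n_words=8,
                                     p_no_taste=0.0)
        assert category_consistency(rec) == naive_category_consistency(rec)

    @given(st.integers(0, 2**31 - 1))
    def test_double_no_taste_word_neutral_for_strict_scorer(self, seed):
        """Appending a double no-taste word leaves the strict percent unchanged
        and never decreases the naive percent."""
        rec = random_category_record(np.random.default_rng(seed), n_words=6,
                                     p_no_taste=0.3)
        try:
            before = category_consistency(rec).percent
        except UndefinedScoreError:
            return
        pairs = [rec.pair(w) for w in rec.words] + [(NT, NT)]
        rec2 = make_category_record(pairs)
        assert category_consistency(rec2).percent == pytest.approx(before)
        assert (naive_category_consistency(rec2).percent
                >= naive_category_consistency(rec).percent - 1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(0, 5))
    def test_upgrading_a_pair_never_decreases_percent(self, seed, idx):
        rng = np.random.default_rng(seed)
        rec = random_category_record(rng, n_words=6, p_no_taste=0.2)
        try:
            before = category_consistency(rec).percent
        except UndefinedScoreError:
            return
        pairs = [rec.pair(w) for w in rec.words]
        r1, _ = pairs[idx]
        if not r1.is_taste:
            return
        pairs[idx] = (r1, r1)  # upgrade to an exact match
        after = category_consistency(make_category_record(pairs)).percent
        assert after >= before - 1e-12


def _pearson_oracle(pairs):
    """Pearson r from the raw-sums formula, independent of numpy.corrcoef."""
    n = len(pairs)
    sx = sum(p[0] for p in pairs)
    sy = sum(p[1] for p in pairs)
    sxx = sum(p[0] ** 2 for p in pairs)
    syy = sum(p[1] ** 2 for p in pairs)
    sxy = sum(p[0] * p[1] for p in pairs)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx**2) * math.sqrt(n * syy - sy**2)
    return num / den


class TestIntensity:
    def test_identical_ratings_give_r_one(self):
        pairs = [(PaletteResponse.taste("Fats", "Butter", i),
                  PaletteResponse.taste("Beverages", "Tea", i))
                 for i in (10, 40, 90)]
        res = intensity_consistency(make_category_record(pairs))
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 3

    def test_exact_reversal_gives_r_minus_one(self):
        pairs = [(PaletteResponse.taste("Fats", "Butter", a),
                  PaletteResponse.taste("Fats", "Butter", b))
                 for a, b in [(10, 30), (20, 20), (30, 10)]]
        assert intensity_consistency(make_category_record(pairs)).r == pytest.approx(-1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_first_principles_oracle(self, seed):
        """Zero-substituted correlation agrees with a raw-sums Pearson oracle."""
        rec = random_category_record(np.random.default_rng(seed), n_words=10,
                                     p_no_taste=0.25)
        pairs = []
        for w in rec.words:
            r1, r2 = rec.pair(w)
            if not r1.is_taste and not r2.is_taste:
                continue  # double no-taste words stay out of the correlation
            pairs.append((r1.intensity if r1.is_taste else 0.0,
                          r2.intensity if r2.is_taste else 0.0))
        try:
            res = intensity_consistency(rec)
        except UndefinedScoreError:
            xs = [p[0] for p in pairs]
            ys = [p[1] for p in pairs]
            assert len(pairs) < 2 or len(set(xs)) == 1 or len(set(ys)) == 1
            return
        assert res.n_pairs == len(pairs)
        assert res.r == pytest.approx(_pearson_oracle(pairs), abs=1e-12)

    def test_zero_variance_is_undefined(self):
        pairs = [(PaletteResponse.taste("Fats", "Butter", 50),
                  PaletteResponse.taste("Fats", "Butter", i)) for i in (10, 60)]
        with pytest.raises(UndefinedScoreError):
            intensity_consistency(make_category_record(pairs))

    def test_mean_intensity(self):
        pairs = [(PaletteResponse.taste("Fats", "Butter", 40), NT),
                 (PaletteResponse.taste("Fats", "Butter", 60),
                  PaletteResponse.taste("Fats", "Butter", 100))]
        rec = make_category_record(pairs)
        assert mean_intensity(rec, 1) == pytest.approx(50.0)
        assert mean_intensity(rec, 2) == pytest.approx(50.0)  # no-taste counts 0
        all_nt = make_category_record([(NT, NT)] * 3)
        assert mean_intensity(all_nt, 1) == 0.0
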