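"""Consistency scoring for the category (hierarchical food palette) scheme.

A word's two responses earn 2 points for an exact match (same category and
same subordinate food), 1 point for a partial match (same category, different
food), and 0 otherwise.  Words answered no-taste in *both* presentations are
excluded from both numerator and denominator — otherwise a respondent who
declines most words would look spuriously consistent.  Words with a taste in
at least one presentation contribute 2 available points each, so

    percent = 100 * points_awarded / (2 * n_words_scored).

A separate intensity-consistency measure correlates the 1-100 intensity
ratings across the two presentations, substituting 0 for the no-taste side of
one-sided no-taste words and dropping double no-taste words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .domain import (
    ParticipantRecord,
    PaletteResponse,
    Scheme,
    UndefinedScoreError,
    ValidationError,
)

__all__ = [
    "EXCLUDED",
    "CategoryConsistencyResult",
    "IntensityConsistencyResult",
    "score_trial_pair",
    "category_consistency",
    "naive_category_consistency",
    "intensity_consistency",
    "mean_intensity",
]

#: Sentinel returned by :func:`score_trial_pair` for a double no-taste word.
EXCLUDED = None


@dataclass(frozen=True)
class CategoryConsistencyResult:
    """Outcome of category-scheme consistency scoring for one participant."""

    participant_id: str
    points_awarded: int
    points_available: int
    n_words_scored: int
    n_double_no_taste: int

    @property
    def percent(self) -> float:
        """Consistency as a percentage of available points."""
        return 100.0 * self.points_awarded / self.points_available

    def __str__(self) -> str:  # 2-decimal rendering, e.g. "45.00%"
        return (
            f"{self.points_awarded}/{self.points_available} points = "
            f"{self.percent:.2f}%"
        )


@dataclass(frozen=True)
class IntensityConsistencyResult:
    """Test-retest correlation of intensity ratings for one participant."""

    participant_id: str
    r: float
    n_pairs: int


def _require_category(record: ParticipantRecord) -> None:
    if record.scheme is not Scheme.CATEGORY:
        raise ValidationError(
            f"participant {record.participant_id}: category scoring needs a "
            f"category-scheme record, got {record.scheme.value}"
        )


def score_trial_pair(
    r1: PaletteResponse, r2: PaletteResponse
) -> Optional[int]:
    """Score one word's pair of responses: 2, 1, 0, or ``EXCLUDED``.

    Exact match (category and food) -> 2; partial match (category only) -> 1;
    different categories, or exactly one no-taste -> 0.  Both responses
    no-taste -> ``EXCLUDED`` (the word is not scored at all).
    """
    if not r1.is_taste and not r2.is_taste:
        return EXCLUDED
    if not r1.is_taste or not r2.is_taste:
        return 0
    if r1.category != r2.category:
        return 0
    return 2 if r1.food == r2.food else 1


def category_consistency(record: ParticipantRecord) -> CategoryConsistencyResult:
    """Score a category-scheme record with the no-taste-exclusion rule.

    Raises
    ------
    UndefinedScoreError
        If every word was answered no-taste in both presentations, so no
        points are available and the percentage is undefined (which is not
        the same thing as a score of 0).
    """
    _require_category(record)
    points = 0
    n_scored = 0
    n_double = 0
    for word in record.words:
        s = score_trial_pair(*record.pair(word))
        if s is EXCLUDED:
            n_double += 1
        else:
            n_scored += 1
            points += s
    if n_scored == 0:
        raise UndefinedScoreError(
            f"participant {record.participant_id}: all {record.n_words} words "
            "were double no-taste; consistency is undefined"
        )
    return CategoryConsistencyResult(
        participant_id=record.participant_id,
        points_awarded=points,
        points_available=2 * n_scored,
        n_words_scored=n_scored,
        n_double_no_taste=n_double,
    )


def naive_category_consistency(
    record: ParticipantRecord,
) -> CategoryConsistencyResult:
    """Score without the no-taste exclusion: the counterfactual variant.

    Double no-taste words count as consistent (2 points) and every word
    contributes to the denominator.  Provided to document why the exclusion
    rule exists — a respondent declining most words scores highly here — not
    for diagnosis.  Identical to :func:`category_consistency` on records with
    no no-taste responses.
    """
    _require_category(record)
    points = 0
    n_double = 0
    for word in record.words:
        s = score_trial_pair(*record.pair(word))
        if s is EXCLUDED:
            n_double += 1
            points += 2
        else:
            points += s
    return CategoryConsistencyResult(
        participant_id=record.participant_id,
        points_awarded=points,
        points_available=2 * record.n_words,
        n_words_scored=record.n_words,
        n_double_no_taste=n_double,
    )


def intensity_pairs(record: ParticipantRecord) -> list[tuple[float, float]]:
    """Paired intensity ratings entering the consistency correlation.

    Per word: both presentations tasted -> (i1, i2); exactly one no-taste ->
    0 substituted on the no-taste side; both no-taste -> the word is dropped.
    """
    _require_category(record)
    pairs = []
    for word in record.words:
        r1, r2 = record.pair(word)
        if not r1.is_taste and not r2.is_taste:
            continue
        i1 = r1.intensity if r1.is_taste else 0.0
        i2 = r2.intensity if r2.is_taste else 0.0
        pairs.append((i1, i2))
    return pairs


def intensity_consistency(record: ParticipantRecord) -> IntensityConsistencyResult:
    """Pearson correlation of intensity ratings across the two presentations.

    Ranges over [-1, 1].  Raises :class:`UndefinedScoreError` when fewer than
    two word pairs survive the double-no-taste exclusion or either
    presentation's included ratings have zero variance.
    """
    pairs = intensity_pairs(record)
    if len(pairs) < 2:
        raise UndefinedScoreError(
            f"participant {record.participant_id}: {len(pairs)} intensity "
            "pair(s) after exclusions; correlation needs at least 2"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedScoreError(
            f"participant {record.participant_id}: zero variance in intensity "
            "ratings; correlation undefined"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return IntensityConsistencyResult(
        participant_id=record.participant_id, r=r, n_pairs=len(pairs)
    )


def mean_intensity(record: ParticipantRecord, presentation: int) -> float:
    """Mean intensity within one presentation, no-taste counted as 0.

    Summary on the 0-100 scale (no-taste words pull the mean toward 0).
    """
    _require_category(record)
    if presentation not in (1, 2):
        raise ValidationError(f"presentation must be 1 or 2, got {presentation}")
    idx = presentation - 1
    vals = [
        record.pair(word)[idx].intensity if record.pair(word)[idx].is_taste else 0.0
        for word in record.words
    ]
    return float(np.mean(vals))
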