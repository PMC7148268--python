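"""Consistency scoring for the five-taste (pie chart) scheme.

Each trial response is a compositional profile — percentages of sweet, sour,
salty, bitter and umami summing to 100.  Consistency is measured per taste by
regressing the 30 presentation-1 percentages against the presentation-2
percentages and taking the coefficient of determination R²; for a simple
linear regression this equals the squared Pearson correlation and is
invariant to which presentation is treated as predictor.  The five R² values
are averaged and expressed as a percentage: the mean share of retest
variability predicted by the first test.

Two data-quality rules apply before the average:

* One-sided no-taste words have the no-taste side replaced by an all-zero
  profile; double no-taste words are dropped entirely (the same rationale as
  the category scheme's exclusion rule: declining words must not look like
  consistency).
* A taste that was assigned (nonzero) on too few words — not more than 10%
  of the word list, i.e. not more than 3 of 30 — is excluded from the
  average, because an R² estimated from a handful of points is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .domain import (
    TASTES,
    ParticipantRecord,
    Scheme,
    TasteProfile,
    UndefinedScoreError,
    ValidationError,
)

__all__ = [
    "TasteConsistencyResult",
    "normalize_profile",
    "taste_r2",
    "taste_consistency",
    "sparse_taste_threshold",
]


def normalize_profile(
    sweet: float, sour: float, salty: float, bitter: float, umami: float
) -> TasteProfile:
    """Rescale five absolute non-negative ratings to a compositional profile.

    Independent absolute ratings (e.g. from five Likert scales) are mapped to
    relative contributions summing to 100: each value is scaled by
    100 / total.  Sour-sweet candy rated (80, 80, 0, 0, 0) absolute becomes
    50% sweet / 50% sour — the pie chart records relative contribution, not
    absolute strength.

    Raises
    ------
    ValidationError
        If any rating is negative or all five are zero (an all-zero vector
        has no relative composition).
    """
    vals = (sweet, sour, salty, bitter, umami)
    if any(v < 0 for v in vals):
        raise ValidationError("ratings must be non-negative")
    total = sum(vals)
    if total == 0:
        raise ValidationError(
            "all five ratings are zero: no relative composition exists"
        )
    scaled = tuple(100.0 * v / total for v in vals)
    return TasteProfile.taste(*scaled)


def taste_r2(x1: Sequence[float], x2: Sequence[float]) -> Optional[float]:
    """Coefficient of determination of the simple regression of x2 on x1.

    Equals the squared Pearson correlation of the paired vectors, hence is
    symmetric in its arguments.  Returns ``None`` (undefined) when either
    vector is constant: with no variance there is nothing to explain.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"paired vectors must have equal length, got {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise ValidationError("need at least 2 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def sparse_taste_threshold(n_words: int) -> float:
    """Minimum assignment count a taste must *exceed* to enter the average.

    A taste is included iff it was assigned (nonzero in at least one
    presentation) on strictly more than 10% of the word list — more than 3
    words for the canonical 30-word instrument.
    """
    return 0.10 * n_words


@dataclass(frozen=True)
class TasteConsistencyResult:
    """Outcome of five-taste consistency scoring for one participant.

    ``per_taste_r2`` maps every taste to its R², or ``None`` where R² is
    undefined (a constant vector).  ``included_tastes`` lists the tastes that
    passed the sparse-assignment rule *and* had a defined R²; only these
    enter ``mean_percent``.  ``sparse_tastes`` and ``undefined_tastes``
    document the exclusions.
    """

    participant_id: str
    per_taste_r2: dict[str, Optional[float]]
    included_tastes: tuple[str, ...]
    sparse_tastes: tuple[str, ...]
    undefined_tastes: tuple[str, ...]
    n_words_used: int
    n_double_no_taste: int

    @property
    def mean_percent(self) -> float:
        """100 x mean R² over the included tastes."""
        vals = [self.per_taste_r2[t] for t in self.included_tastes]
        return 100.0 * float(np.mean(vals))

    def __str__(self) -> str:
        return f"{self.mean_percent:.2f}% over {len(self.included_tastes)} tastes"


def taste_consistency(
    record: ParticipantRecord, apply_sparse_rule: bool = True
) -> TasteConsistencyResult:
    """Score a five-taste record: mean per-taste test-retest R², as a percent.

    Parameters
    ----------
    record
        A validated five-taste-scheme record.
    apply_sparse_rule
        When False, rarely-assigned tastes are kept in the average (used to
        audit that the sparse-taste rule does not systematically favor either
        group); undefined-R² tastes are always dropped.

    Raises
    ------
    UndefinedScoreError
        When fewer than two words survive the double-no-taste exclusion, or
        no taste is both included and has a defined R².
    """
    if record.scheme is not Scheme.FIVE_TASTE:
        raise ValidationError(
            f"participant {record.participant_id}: five-taste scoring needs a "
            f"five_taste-scheme record, got {record.scheme.value}"
        )
    zero = (0.0,) * 5
    rows1, rows2 = [], []
    n_double = 0
    for word in record.words:
        p1, p2 = record.pair(word)
        if not p1.is_taste and not p2.is_taste:
            n_double += 1
            continue
        rows1.append(p1.values if p1.is_taste else zero)
        rows2.append(p2.values if p2.is_taste else zero)
    n_used = len(rows1)
    if n_used < 2:
        raise UndefinedScoreError(
            f"participant {record.participant_id}: only {n_used} usable "
            "word(s) after double no-taste exclusion"
        )
    m1 = np.array(rows1)  # (n_used, 5), presentation 1
    m2 = np.array(rows2)

    threshold = sparse_taste_threshold(record.n_words)
    assigned = ((m1 > 0) | (m2 > 0)).sum(axis=0)  # nonzero in either presentation

    per_taste: dict[str, Optional[float]] = {}
    included, sparse, undefined = [], [], []
    for j, taste in enumerate(TASTES):
        r2 = taste_r2(m1[:, j], m2[:, j])
        per_taste[taste] = r2
        if apply_sparse_rule and not assigned[j] > threshold:
            sparse.append(taste)
        elif r2 is None:
            undefined.append(taste)
        else:
            included.append(taste)
    if not included:
        raise UndefinedScoreError(
            f"participant {record.participant_id}: no taste with a defined R² "
            "survives the sparse-assignment rule; score undefined"
        )
    return TasteConsistencyResult(
        participant_id=record.participant_id,
        per_taste_r2=per_taste,
        included_tastes=tuple(included),
        sparse_tastes=tuple(sparse),
        undefined_tastes=tuple(undefined),
        n_words_used=n_used,
        n_double_no_taste=n_double,
    )
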