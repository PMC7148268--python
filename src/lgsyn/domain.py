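"""Core data model for the lexical-gustatory consistency test.

Two response schemes are supported, matching the two variants of the
instrument:

* ``category`` — the respondent picks a food from a hierarchical palette
  (superordinate category, then subordinate food) and rates the intensity of
  the word-flavor association on a 1-100 slider, or presses a no-taste button.
* ``five_taste`` — the respondent describes the associated food as a
  compositional profile over the five basic tastes (sweet, sour, salty,
  bitter, umami) summing to 100%, or declares no taste.

Every participant sees the word list twice (two blocked presentations);
consistency between the paired responses is the diagnostic signal.  The
self-report questionnaire preceding the objective test yields a provisional
label (projector synesthete, associator synesthete, or nonsynesthete) that
the ROC evaluation treats as ground truth.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "TASTES",
    "Scheme",
    "ValidationError",
    "UndefinedScoreError",
    "FoodPalette",
    "PaletteResponse",
    "TasteProfile",
    "SelfReport",
    "SynStatus",
    "ParticipantRecord",
    "load_palette",
    "save_palette",
    "default_word_list",
    "classify_self_report",
    "validate_record",
]

#: Canonical order of the five basic tastes in a compositional profile.
TASTES = ("sweet", "sour", "salty", "bitter", "umami")

PROFILE_SUM_TOL = 1e-6


class Scheme(str, enum.Enum):
    """Which response format a record uses."""

    CATEGORY = "category"
    FIVE_TASTE = "five_taste"


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


class UndefinedScoreError(ValueError):
    """A score or correlation is mathematically undefined for this record.

    Raised instead of returning 0: a score of 0 is a legitimate (bad)
    result, whereas an undefined one carries no information and must not be
    silently conflated with it.
    """


def _norm(name: str) -> str:
    """Whitespace-normalize a name: strip ends, collapse internal runs."""
    return re.sub(r"\s+", " ", name.strip())


# ---------------------------------------------------------------------------
# Food palette
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodPalette:
    """Hierarchical inventory of foods: ordered categories, each with foods.

    Food identity for matching is the (category, food) pair, case-sensitive
    after whitespace normalization.  The packaged default palette has 11
    superordinate categories and 87 subordinate foods.
    """

    categories: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen_cats: set[str] = set()
        for cat, foods in self.categories:
            if not cat:
                raise ValidationError("empty category name")
            if cat in seen_cats:
                raise ValidationError(f"duplicate category name: {cat!r}")
            seen_cats.add(cat)
            if not foods:
                raise ValidationError(f"category {cat!r} has no foods")
            seen_foods: set[str] = set()
            for food in foods:
                if not food:
                    raise ValidationError(f"empty food name in {cat!r}")
                if food in seen_foods:
                    raise ValidationError(
                        f"duplicate food name {food!r} in category {cat!r}"
                    )
                seen_foods.add(food)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_foods(self) -> int:
        return sum(len(foods) for _, foods in self.categories)

    def category_names(self) -> tuple[str, ...]:
        return tuple(cat for cat, _ in self.categories)

    def foods_in(self, category: str) -> tuple[str, ...]:
        for cat, foods in self.categories:
            if cat == category:
                return foods
        raise KeyError(category)

    def __contains__(self, item: tuple[str, str]) -> bool:
        cat, food = item
        for name, foods in self.categories:
            if name == cat:
                return food in foods
        return False

    def to_dict(self) -> dict:
        return {
            "categories": [
                {"name": cat, "foods": list(foods)} for cat, foods in self.categories
            ]
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FoodPalette":
        try:
            cats = doc["categories"]
        except (KeyError, TypeError):
            raise ValidationError("palette document must have a 'categories' key")
        parsed = []
        for entry in cats:
            try:
                name = _norm(str(entry["name"]))
                foods = tuple(_norm(str(f)) for f in entry["foods"])
            except (KeyError, TypeError):
                raise ValidationError(
                    "each category needs 'name' and a 'foods' list"
                )
            parsed.append((name, foods))
        return cls(categories=tuple(parsed))


def load_palette(source: Union[str, Path, Mapping, None] = None) -> FoodPalette:
    """Load and validate a food palette.

    Parameters
    ----------
    source
        Path to a YAML or JSON palette document of shape
        ``{categories: [{name, foods: [...]}, ...]}``, or an already-parsed
        mapping.  ``None`` (the default) loads the packaged 11-category /
        87-food palette.
    """
    if source is None:
        text = (
            resources.files("lgsyn.data").joinpath("palette.yaml").read_text("utf-8")
        )
        doc = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        doc = source
    else:
        doc = yaml.safe_load(Path(source).read_text("utf-8"))
    return FoodPalette.from_dict(doc)


def save_palette(palette: FoodPalette, path: Union[str, Path]) -> None:
    """Write a palette document (YAML) that :func:`load_palette` round-trips."""
    Path(path).write_text(
        yaml.safe_dump(palette.to_dict(), sort_keys=False, allow_unicode=True),
        "utf-8",
    )


def default_word_list() -> tuple[str, ...]:
    """The packaged synthetic 30-word stimulus list.

    A synthetic stand-in with the canonical instrument's shape (30 common,
    early-acquired English words); scoring accepts any word list with n >= 1.
    """
    text = (
        resources.files("lgsyn.data")
        .joinpath("words_synthetic_30.txt")
        .read_text("utf-8")
    )
    return tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


# ---------------------------------------------------------------------------
# Trial responses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaletteResponse:
    """One trial's answer under the category scheme.

    Either a taste response — a (category, food) choice from the palette plus
    an intensity on the 1 (very weak) to 100 (extremely strong) slider — or a
    no-taste declaration.
    """

    kind: str  # "taste" | "no_taste"
    category: Optional[str] = None
    food: Optional[str] = None
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "no_taste":
            if self.category is not None or self.food is not None or self.intensity is not None:
                raise ValidationError("no_taste response must not carry a payload")
        elif self.kind == "taste":
            if self.category is None or self.food is None or self.intensity is None:
                raise ValidationError(
                    "taste response requires category, food and intensity"
                )
            if not (1 <= self.intensity <= 100):
                raise ValidationError(
                    f"intensity {self.intensity} outside [1, 100]"
                )
            object.__setattr__(self, "category", _norm(self.category))
            object.__setattr__(self, "food", _norm(self.food))
        else:
            raise ValidationError(f"unknown response kind: {self.kind!r}")

    @property
    def is_taste(self) -> bool:
        return self.kind == "taste"

    @classmethod
    def taste(cls, category: str, food: str, intensity: float) -> "PaletteResponse":
        return cls("taste", category, food, intensity)

    @classmethod
    def no_taste(cls) -> "PaletteResponse":
        return cls("no_taste")


@dataclass(frozen=True)
class TasteProfile:
    """One trial's answer under the five-taste scheme.

    A compositional profile: five non-negative percentages over sweet, sour,
    salty, bitter and umami that sum to 100 — or a no-taste declaration.
    """

    kind: str  # "taste" | "no_taste"
    sweet: float = 0.0
    sour: float = 0.0
    salty: float = 0.0
    bitter: float = 0.0
    umami: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "no_taste":
            if any(v != 0 for v in self.values):
                raise ValidationError("no_taste profile must be all zero")
            return
        if self.kind != "taste":
            raise ValidationError(f"unknown response kind: {self.kind!r}")
        if any(v < 0 for v in self.values):
            raise ValidationError("taste percentages must be non-negative")
        total = sum(self.values)
        if abs(total - 100.0) > PROFILE_SUM_TOL:
            raise ValidationError(
                f"taste profile sums to {total}, not 100 (tolerance {PROFILE_SUM_TOL})"
            )

    @property
    def values(self) -> tuple[float, float, float, float, float]:
        return (self.sweet, self.sour, self.salty, self.bitter, self.umami)

    @property
    def is_taste(self) -> bool:
        return self.kind == "taste"

    @classmethod
    def taste(cls, sweet: float, sour: float, salty: float, bitter: float,
              umami: float) -> "TasteProfile":
        return cls("taste", sweet, sour, salty, bitter, umami)

    @classmethod
    def no_taste(cls) -> "TasteProfile":
        return cls("no_taste")


# ---------------------------------------------------------------------------
# Self-report
# ---------------------------------------------------------------------------


class SynStatus(str, enum.Enum):
    """Self-report classification of a participant."""

    PROJECTOR = "projector_synesthete"
    ASSOCIATOR = "associator_synesthete"
    NONSYNESTHETE = "nonsynesthete"

    @property
    def is_synesthete(self) -> bool:
        return self is not SynStatus.NONSYNESTHETE


@dataclass(frozen=True)
class SelfReport:
    """Answers to the two-step self-report questionnaire.

    ``initial_answer`` is the yes/no to having felt since childhood that
    words have their own tastes.  A "yes" branches to a follow-up: flavors
    experienced in the mouth, thoughts arising in the mind, or a retraction
    ("made a mistake").  A "no" has no applicable follow-up.
    """

    initial_answer: str  # "yes" | "no"
    followup: str  # "flavors_in_mouth" | "thoughts_in_mind" | "made_a_mistake" | "not_applicable"
    examples: tuple[tuple[str, str], ...] = ()

    _FOLLOWUPS = ("flavors_in_mouth", "thoughts_in_mind", "made_a_mistake",
                  "not_applicable")

    def __post_init__(self) -> None:
        if self.initial_answer not in ("yes", "no"):
            raise ValidationError(
                f"initial_answer must be yes/no, got {self.initial_answer!r}"
            )
        if self.followup not in self._FOLLOWUPS:
            raise ValidationError(f"unknown followup: {self.followup!r}")
        if (self.followup == "not_applicable") != (self.initial_answer == "no"):
            raise ValidationError(
                "followup must be not_applicable exactly when initial_answer is no"
            )


def classify_self_report(report: SelfReport) -> SynStatus:
    """Map questionnaire answers to a synesthete status label.

    "Yes" followed by flavors in the mouth yields a projector synesthete;
    "yes" followed by thoughts in the mind an associator; everything else
    (an initial "no", or a "yes" retracted as a mistake) a nonsynesthete.
    """
    if report.initial_answer == "no":
        return SynStatus.NONSYNESTHETE
    if report.followup == "flavors_in_mouth":
        return SynStatus.PROJECTOR
    if report.followup == "thoughts_in_mind":
        return SynStatus.ASSOCIATOR
    return SynStatus.NONSYNESTHETE  # "made_a_mistake"


# ---------------------------------------------------------------------------
# Participant record
# ---------------------------------------------------------------------------

Response = Union[PaletteResponse, TasteProfile]


@dataclass(frozen=True)
class ParticipantRecord:
    """All trial responses of one participant: word -> (presentation 1, 2).

    The canonical instrument uses 30 words, but any n >= 1 is scored.
    """

    participant_id: str
    scheme: Scheme
    words: tuple[str, ...]
    responses: Mapping[str, tuple[Response, Response]]
    self_report: Optional[SelfReport] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if not self.words:
            raise ValidationError(
                f"participant {self.participant_id}: empty word list"
            )
        if len(set(self.words)) != len(self.words):
            raise ValidationError(
                f"participant {self.participant_id}: duplicate words"
            )
        expected = (
            PaletteResponse if self.scheme is Scheme.CATEGORY else TasteProfile
        )
        for word in self.words:
            pair = self.responses.get(word)
            if pair is None or len(pair) != 2:
                raise ValidationError(
                    f"participant {self.participant_id}, word {word!r}: "
                    "need exactly one response per presentation"
                )
            for resp in pair:
                if not isinstance(resp, expected):
                    raise ValidationError(
                        f"participant {self.participant_id}, word {word!r}: "
                        f"response type does not match scheme {self.scheme.value}"
                    )
        extra = set(self.responses) - set(self.words)
        if extra:
            raise ValidationError(
                f"participant {self.participant_id}: responses for unknown "
                f"words {sorted(extra)}"
            )

    def pair(self, word: str) -> tuple[Response, Response]:
        return self.responses[word]

    @property
    def n_words(self) -> int:
        return len(self.words)


def validate_record(record: ParticipantRecord,
                    palette: Optional[FoodPalette] = None) -> ParticipantRecord:
    """Validate a record, including palette membership of every food choice.

    Structural invariants are enforced at construction; this adds the check
    that every (category, food) pair of a category-scheme record exists in
    ``palette``.  Returns the record unchanged on success.
    """
    if record.scheme is Scheme.CATEGORY and palette is not None:
        problems = []
        for word in record.words:
            for pres, resp in zip((1, 2), record.pair(word)):
                if resp.is_taste and (resp.category, resp.food) not in palette:
                    problems.append(
                        f"word {word!r} presentation {pres}: "
                        f"({resp.category!r}, {resp.food!r}) not in palette"
                    )
        if problems:
            raise ValidationError(
                f"participant {record.participant_id}: " + "; ".join(problems)
            )
    return record
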