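"""Tiny built-in records for demos and worked examples.

These encode the scoring rules' canonical hand-checkable cases: a 30-word
category record whose composition (4 exact matches, 1 partial match, 5
mismatches, 20 double no-taste words) scores 9/20 = 45.00% under the
no-taste-exclusion rule and 49/60 under the naive variant, and a small
five-taste record convenient for tracing the per-taste R² computation.
"""

from __future__ import annotations

from .domain import (
    ParticipantRecord,
    PaletteResponse,
    Scheme,
    SelfReport,
    TasteProfile,
)

__all__ = ["worked_example_record", "toy_five_taste_record"]


def worked_example_record(participant_id: str = "example") -> ParticipantRecord:
    """The canonical category-scheme worked example.

    30 words: 4 exact matches (2 points each), 1 partial match (1 point),
    5 category mismatches (0), and 20 words answered no-taste in both
    presentations.  Ten words received at least one food, so 20 points are
    available and the consistency score is 9/20 = 45.00%; the naive variant
    credits the 20 double no-taste words too, giving 49/60.
    """
    butter = PaletteResponse.taste("Fats", "Butter", 60)
    veg_fat = PaletteResponse.taste("Fats", "Vegetable fat (e.g., margarine)", 55)
    mismatches = [
        (PaletteResponse.taste("Beverages", "Coffee", 70),
         PaletteResponse.taste("Sugar/Sugar Products", "Chocolate", 40)),
        (PaletteResponse.taste("Eggs/Dairy", "Cheese", 50),
         PaletteResponse.taste("Bakery/Cereals", "Pasta", 45)),
        (PaletteResponse.taste("Fruits and Nuts", "Citrus", 80),
         PaletteResponse.taste("Condiments/Sauces/Soups", "Vinegar", 30)),
        (PaletteResponse.taste("Meat/Meat Products", "Poultry", 65),
         PaletteResponse.taste("Fish/Seafood", "Seafood", 35)),
        (PaletteResponse.taste("Vegetables (incl. Pulses, Potatoes)", "Tomatoes", 25),
         PaletteResponse.taste("Beverages", "Tea", 75)),
    ]
    words = tuple(f"w{i:02d}" for i in range(1, 31))
    responses = {}
    for i, word in enumerate(words):
        if i < 4:  # exact matches
            responses[word] = (butter, butter)
        elif i < 5:  # partial match: same category, different food
            responses[word] = (butter, veg_fat)
        elif i < 10:  # category mismatches
            responses[word] = mismatches[i - 5]
        else:  # double no-taste
            responses[word] = (PaletteResponse.no_taste(),
                               PaletteResponse.no_taste())
    return ParticipantRecord(
        participant_id=participant_id,
        scheme=Scheme.CATEGORY,
        words=words,
        responses=responses,
        self_report=SelfReport("no", "not_applicable"),
    )


def toy_five_taste_record(participant_id: str = "toy") -> ParticipantRecord:
    """A fixed 6-word five-taste record for tracing the R² computation.

    Includes a one-sided no-taste word (zero-substituted on the missing
    side) and a double no-taste word (dropped entirely).  At 6 words the
    sparse-taste rule's 10% threshold admits any taste assigned at least
    once, so all five tastes enter the average.
    """
    t = TasteProfile.taste
    nt = TasteProfile.no_taste()
    words = ("w1", "w2", "w3", "w4", "w5", "w6")
    responses = {
        "w1": (t(50, 50, 0, 0, 0), t(60, 40, 0, 0, 0)),
        "w2": (t(0, 0, 80, 0, 20), t(10, 0, 70, 0, 20)),
        "w3": (t(100, 0, 0, 0, 0), t(90, 10, 0, 0, 0)),
        "w4": (t(20, 0, 30, 0, 50), nt),
        "w5": (t(0, 30, 20, 50, 0), t(0, 40, 20, 40, 0)),
        "w6": (nt, nt),
    }
    return ParticipantRecord(
        participant_id=participant_id,
        scheme=Scheme.FIVE_TASTE,
        words=words,
        responses=responses,
        self_report=SelfReport("yes", "thoughts_in_mind"),
    )
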