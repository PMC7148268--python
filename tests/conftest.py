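import hypothesis
import numpy as np
import pytest

from lgsyn import (
    ParticipantRecord,
    PaletteResponse,
    Scheme,
    TasteProfile,
    load_palette,
)
from lgsyn.fixtures import toy_five_taste_record, worked_example_record

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    deadline=None,
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def palette():
    return load_palette()


@pytest.fixture()
def worked_example():
    return worked_example_record()


@pytest.fixture()
def toy_taste_record():
    return toy_five_taste_record()


def make_category_record(pairs, participant_id="p", self_report=None):
    """Build a category-scheme record from a list of response pairs."""
    words = tuple(f"w{i:02d}" for i in range(len(pairs)))
    return ParticipantRecord(
        participant_id=participant_id,
        scheme=Scheme.CATEGORY,
        words=words,
        responses=dict(zip(words, pairs)),
        self_report=self_report,
    )


def make_taste_record(pairs, participant_id="p"):
    """Build a five-taste record from a list of (TasteProfile, TasteProfile)."""
    words = tuple(f"w{i:02d}" for i in range(len(pairs)))
    return ParticipantRecord(
        participant_id=participant_id,
        scheme=Scheme.FIVE_TASTE,
        words=words,
        responses=dict(zip(words, pairs)),
    )


def random_category_record(rng, n_words=12, p_no_taste=0.2, participant_id="p"):
    """A random but valid category record drawn from the packaged palette."""
    pal = load_palette()
    foods = [(c, f) for c, fs in pal.categories for f in fs]

    def draw():
        if rng.random() < p_no_taste:
            return PaletteResponse.no_taste()
        c, f = foods[rng.integers(len(foods))]
        return PaletteResponse.taste(c, f, float(rng.integers(1, 101)))

    return make_category_record(
        [(draw(), draw()) for _ in range(n_words)], participant_id
    )


def random_profile(rng):
    v = rng.dirichlet(np.full(5, 0.8)) * 100.0
    return TasteProfile.taste(*v)
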