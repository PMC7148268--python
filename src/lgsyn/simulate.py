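"""Seeded synthetic cohorts with the response structure the instrument assumes.

No distributional model of real responders exists, so the generator is an
explicit invention calibrated to the instrument's published group medians.
It emulates the features the scorers care about:

* a latent word-flavor association per word, repeated across the two
  presentations with a tunable fidelity (``p_exact`` / ``p_partial`` for the
  category scheme, a Dirichlet ``concentration`` for taste profiles);
* no-taste responses at a per-presentation rate ``1 - p_taste``;
* intensity ratings on the 1-100 slider, a latent level per word plus
  independent per-presentation Gaussian noise;
* compositional five-taste profiles summing to 100.

Synesthetes are high-fidelity responders, controls low-fidelity ones; the
default parameters live in ``data/defaults.yaml`` and were calibrated by
Monte-Carlo against the published group medians (category scheme: ~85.9 vs.
~45.0; five-taste: ~67.8 vs. ~13.3).  The RNG is numpy's PCG64; a seed fully
determines the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .domain import (
    FoodPalette,
    ParticipantRecord,
    PaletteResponse,
    Scheme,
    SelfReport,
    SynStatus,
    TasteProfile,
    ValidationError,
    load_palette,
)

__all__ = [
    "ResponderParams",
    "SimulationConfig",
    "default_params",
    "default_cutoff",
    "simulate_participant",
    "simulate_cohort",
]

RNG_ALGORITHM = "PCG64"

#: Floor added to Dirichlet concentrations so zero components stay feasible
#: (mirrors the pie-chart widget, whose segments start at >= 1 percent).
_DIRICHLET_FLOOR = 0.01


def _load_defaults() -> dict:
    text = resources.files("lgsyn.data").joinpath("defaults.yaml").read_text("utf-8")
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ResponderParams:
    """Behavioral parameters of one simulated responder group.

    p_taste
        Probability a word receives a taste (vs. no-taste) in each
        presentation, independently.
    p_exact, p_partial
        Category scheme: probability presentation 2 repeats presentation 1's
        latent food exactly / stays in-category but switches food.  With the
        remaining mass a fresh uniform food is drawn.
    intensity_mu, intensity_sd
        Location and scale of the latent per-word intensity on the 1-100
        slider.
    intensity_noise_sd
        Scale of the independent per-presentation rating noise.
    concentration
        Five-taste scheme: Dirichlet precision with which each presentation
        re-draws around the word's latent profile; larger is more faithful.
    profile_sparsity
        Symmetric Dirichlet parameter of the latent profile; below 1 favors
        profiles dominated by one or two tastes, as food flavors are.
    """

    p_taste: float = 1.0
    p_exact: float = 1.0
    p_partial: float = 0.0
    intensity_mu: float = 50.0
    intensity_sd: float = 15.0
    intensity_noise_sd: float = 10.0
    concentration: float = 50.0
    profile_sparsity: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_taste", "p_exact", "p_partial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.p_exact + self.p_partial > 1.0 + 1e-12:
            raise ValidationError("p_exact + p_partial must not exceed 1")
        if not 1.0 <= self.intensity_mu <= 100.0:
            raise ValidationError("intensity_mu must lie in [1, 100]")
        if self.intensity_sd < 0 or self.intensity_noise_sd < 0:
            raise ValidationError("intensity scales must be non-negative")
        if self.concentration <= 0 or self.profile_sparsity <= 0:
            raise ValidationError("concentration and sparsity must be > 0")


def default_params(scheme: Scheme | str, group: str) -> ResponderParams:
    """Packaged calibrated parameters for ``group`` in {synesthete, control}."""
    scheme = Scheme(scheme)
    doc = _load_defaults()["simulator"][scheme.value]
    if group not in doc:
        raise ValidationError(f"unknown simulator group: {group!r}")
    return ResponderParams(**doc[group])


def default_cutoff(scheme: Scheme | str) -> float:
    """Packaged recommended diagnostic cutoff for a scheme."""
    return float(_load_defaults()["cutoffs"][Scheme(scheme).value])


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a synthetic cohort (given the seed)."""

    scheme: Scheme = Scheme.CATEGORY
    n_syn: int = 28
    n_control: int = 57
    n_words: int = 30
    seed: int = 0
    syn_params: Optional[ResponderParams] = None
    control_params: Optional[ResponderParams] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        if self.n_syn < 0 or self.n_control < 0:
            raise ValidationError("group sizes must be >= 0")
        if self.n_syn == 0 and self.n_control == 0:
            raise ValidationError("at least one group must be non-empty")
        if self.n_words < 1:
            raise ValidationError("n_words must be >= 1")
        if self.syn_params is None:
            object.__setattr__(
                self, "syn_params", default_params(self.scheme, "synesthete")
            )
        if self.control_params is None:
            object.__setattr__(
                self, "control_params", default_params(self.scheme, "control")
            )

    def describe(self) -> dict:
        """Reproducibility metadata, including the pinned RNG algorithm."""
        return {
            "scheme": self.scheme.value,
            "n_syn": self.n_syn,
            "n_control": self.n_control,
            "n_words": self.n_words,
            "seed": self.seed,
            "rng_algorithm": RNG_ALGORITHM,
            "syn_params": vars(self.syn_params).copy(),
            "control_params": vars(self.control_params).copy(),
        }


def _clamp_intensity(x: float) -> float:
    return float(min(100.0, max(1.0, x)))


def _flat_foods(palette: FoodPalette) -> list[tuple[str, str]]:
    return [(cat, food) for cat, foods in palette.categories for food in foods]


def _simulate_category(
    params: ResponderParams,
    words: tuple[str, ...],
    rng: np.random.Generator,
    palette: FoodPalette,
) -> dict[str, tuple[PaletteResponse, PaletteResponse]]:
    foods = _flat_foods(palette)
    responses = {}
    for word in words:
        cat, food = foods[rng.integers(len(foods))]
        latent_i = rng.normal(params.intensity_mu, params.intensity_sd)

        def emit(cat_: str, food_: str) -> PaletteResponse:
            i = _clamp_intensity(latent_i + rng.normal(0.0, params.intensity_noise_sd))
            return PaletteResponse.taste(cat_, food_, i)

        # presentation 1: the latent association, or no-taste
        r1 = emit(cat, food) if rng.random() < params.p_taste else PaletteResponse.no_taste()

        # presentation 2: repeat exactly / in-category / fresh draw
        if rng.random() < params.p_taste:
            u = rng.random()
            if u < params.p_exact:
                cat2, food2 = cat, food
            elif u < params.p_exact + params.p_partial:
                others = [f for f in palette.foods_in(cat) if f != food]
                food2 = others[rng.integers(len(others))] if others else food
                cat2 = cat
            else:
                cat2, food2 = foods[rng.integers(len(foods))]
            r2 = emit(cat2, food2)
        else:
            r2 = PaletteResponse.no_taste()
        responses[word] = (r1, r2)
    return responses


def _simulate_five_taste(
    params: ResponderParams,
    words: tuple[str, ...],
    rng: np.random.Generator,
) -> dict[str, tuple[TasteProfile, TasteProfile]]:
    responses = {}
    alpha0 = np.full(5, params.profile_sparsity)
    for word in words:
        latent = rng.dirichlet(alpha0)

        def emit() -> TasteProfile:
            alpha = params.concentration * latent + _DIRICHLET_FLOOR
            vals = rng.dirichlet(alpha) * 100.0  # sums to 100 within fp error
            return TasteProfile.taste(*vals)

        r1 = emit() if rng.random() < params.p_taste else TasteProfile.no_taste()
        r2 = emit() if rng.random() < params.p_taste else TasteProfile.no_taste()
        responses[word] = (r1, r2)
    return responses


def _self_report(status: SynStatus) -> SelfReport:
    if status is SynStatus.PROJECTOR:
        return SelfReport("yes", "flavors_in_mouth")
    if status is SynStatus.ASSOCIATOR:
        return SelfReport("yes", "thoughts_in_mind")
    return SelfReport("no", "not_applicable")


def simulate_participant(
    params: ResponderParams,
    scheme: Scheme | str,
    n_words: int,
    rng: np.random.Generator,
    participant_id: str = "sim",
    status: SynStatus = SynStatus.NONSYNESTHETE,
    palette: Optional[FoodPalette] = None,
) -> ParticipantRecord:
    """Draw one participant's full two-presentation record.

    Deterministic given the generator state: the same seeded generator
    produces the identical record on repeat calls.
    """
    scheme = Scheme(scheme)
    words = tuple(f"w{i + 1:02d}" for i in range(n_words))
    if scheme is Scheme.CATEGORY:
        responses = _simulate_category(
            params, words, rng, palette if palette is not None else load_palette()
        )
    else:
        responses = _simulate_five_taste(params, words, rng)
    return ParticipantRecord(
        participant_id=participant_id,
        scheme=scheme,
        words=words,
        responses=responses,
        self_report=_self_report(status),
    )


def _status_sequence(n_syn: int, n_control: int) -> list[SynStatus]:
    # Published recruitment split 17 projectors / 11 associators at n_syn=28;
    # otherwise an even split.  Cosmetic: no score depends on the sub-label.
    if n_syn == 28:
        n_proj = 17
    else:
        n_proj = (n_syn + 1) // 2
    return (
        [SynStatus.PROJECTOR] * n_proj
        + [SynStatus.ASSOCIATOR] * (n_syn - n_proj)
        + [SynStatus.NONSYNESTHETE] * n_control
    )


def simulate_cohort(
    config: SimulationConfig,
) -> list[tuple[ParticipantRecord, SynStatus]]:
    """Draw a labeled cohort: synesthetes first, then controls.

    Fully reproducible from ``config.seed`` (PCG64).  Participant ids are
    ``syn###`` / ``ctl###``.
    """
    rng = np.random.default_rng(config.seed)
    palette = load_palette() if config.scheme is Scheme.CATEGORY else None
    out = []
    n_syn_seen = 0
    for i, status in enumerate(_status_sequence(config.n_syn, config.n_control)):
        if status.is_synesthete:
            n_syn_seen += 1
            pid = f"syn{n_syn_seen:03d}"
            params = config.syn_params
        else:
            pid = f"ctl{i - config.n_syn + 1:03d}"
            params = config.control_params
        record = simulate_participant(
            params, config.scheme, config.n_words, rng,
            participant_id=pid, status=status, palette=palette,
        )
        out.append((record, status))
    return out
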