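"""ROC evaluation of a consistency score against self-report labels.

Self-report (synesthete vs. nonsynesthete) is treated as ground truth and
the consistency score as the diagnostic predictor.  For every candidate
cutoff — each distinct observed score, plus one sentinel below the minimum —
a participant is classified synesthete when their score is *strictly
greater* than the cutoff.  Then per cutoff:

* sensitivity  = P(score > cutoff | synesthete)        (hit rate)
* specificity  = P(score <= cutoff | nonsynesthete)    (correct rejection)
* efficiency   = (TP + TN) / N, the proportion of participants classified
  in line with their self-report — the criterion used to pick the
  recommended threshold.

AUC is computed in the rank (Mann-Whitney) formulation: the probability that
a randomly chosen synesthete outscores a randomly chosen nonsynesthete,
ties credited 1/2.  It runs from .5 (guessing) to 1 (perfect separation) and
equals the trapezoidal area under the strict-threshold ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.stats import rankdata

from .domain import SynStatus, ValidationError

__all__ = [
    "LabeledScore",
    "RocPoint",
    "RocResult",
    "roc_points",
    "auc",
    "max_efficiency_cutoff",
    "roc_analysis",
    "classify",
]

SYN = "synesthete"
NON = "nonsynesthete"


def _binary_label(label: Union[str, SynStatus]) -> str:
    if isinstance(label, SynStatus):
        return SYN if label.is_synesthete else NON
    if label in (SYN, NON):
        return label
    try:
        return SYN if SynStatus(label).is_synesthete else NON
    except ValueError:
        raise ValidationError(f"unknown label: {label!r}")


@dataclass(frozen=True)
class LabeledScore:
    """One participant's consistency score with their self-report label.

    Projector and associator sub-labels both count as synesthete: the
    diagnostic question is presence, not subtype.
    """

    participant_id: str
    score: float
    label: str  # "synesthete" | "nonsynesthete"

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError(
                f"participant {self.participant_id}: score must be finite"
            )
        object.__setattr__(self, "label", _binary_label(self.label))


@dataclass(frozen=True)
class RocPoint:
    """Operating characteristics of the test at one cutoff."""

    cutoff: float
    sensitivity: float
    specificity: float
    efficiency: float

    @property
    def youden_j(self) -> float:
        """Youden's J = sensitivity + specificity - 1 (convenience only)."""
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class RocResult:
    """Full ROC evaluation: per-cutoff points, AUC, recommended cutoff."""

    points: tuple[RocPoint, ...]
    auc: float
    optimal_point: RocPoint

    @property
    def optimal_cutoff(self) -> float:
        return self.optimal_point.cutoff


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    syn = np.array([s.score for s in scores if s.label == SYN], dtype=float)
    non = np.array([s.score for s in scores if s.label == NON], dtype=float)
    if syn.size == 0 or non.size == 0:
        raise ValidationError(
            "ROC needs at least one score per label "
            f"(got {syn.size} synesthete, {non.size} nonsynesthete)"
        )
    return syn, non


def roc_points(scores: Sequence[LabeledScore]) -> list[RocPoint]:
    """One operating point per candidate cutoff, in increasing cutoff order.

    Candidate cutoffs are all distinct observed scores plus a sentinel one
    unit below the minimum (at which everyone is classified synesthete:
    sensitivity 1, specificity 0).
    """
    syn, non = _split(scores)
    observed = np.unique(np.concatenate([syn, non]))
    cutoffs = np.concatenate([[observed[0] - 1.0], observed])
    n = syn.size + non.size
    out = []
    for c in cutoffs:
        tp = int((syn > c).sum())
        tn = int((non <= c).sum())
        out.append(
            RocPoint(
                cutoff=float(c),
                sensitivity=tp / syn.size,
                specificity=tn / non.size,
                efficiency=(tp + tn) / n,
            )
        )
    return out


def auc(scores: Sequence[LabeledScore]) -> float:
    """Rank-based AUC: P(random synesthete outscores random nonsynesthete).

    Mann-Whitney formulation with ties credited 1/2; identical to the
    trapezoidal area under the strict-threshold ROC curve.
    """
    syn, non = _split(scores)
    pooled = np.concatenate([syn, non])
    ranks = rankdata(pooled)  # average ranks on ties -> half credit
    r_syn = ranks[: syn.size].sum()
    u = r_syn - syn.size * (syn.size + 1) / 2.0
    return float(u / (syn.size * non.size))


def max_efficiency_cutoff(points: Iterable[RocPoint]) -> RocPoint:
    """The operating point with maximum efficiency.

    The recommended diagnostic threshold: it passes the largest share of
    self-declared synesthetes while passing the smallest share of
    nonsynesthetes.  Ties are broken toward higher sensitivity, then toward
    the lower cutoff.
    """
    pts = list(points)
    if not pts:
        raise ValidationError("no ROC points supplied")
    return max(pts, key=lambda p: (p.efficiency, p.sensitivity, -p.cutoff))


def roc_analysis(scores: Sequence[LabeledScore]) -> RocResult:
    """Full ROC evaluation of labeled consistency scores."""
    pts = roc_points(scores)
    return RocResult(
        points=tuple(pts),
        auc=auc(scores),
        optimal_point=max_efficiency_cutoff(pts),
    )


def classify(score: float, cutoff: float) -> str:
    """Diagnose at a threshold: strictly above the cutoff -> synesthete."""
    if not (np.isfinite(score) and np.isfinite(cutoff)):
        raise ValidationError("score and cutoff must be finite")
    return SYN if score > cutoff else NON


def plot_roc(result: RocResult, path, title: str = "ROC curve") -> None:
    """Write an ROC curve plot (SVG/PNG by extension); needs matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [1 - p.specificity for p in result.points]
    tpr = [p.sensitivity for p in result.points]
    order = np.argsort(fpr)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(np.asarray(fpr)[order], np.asarray(tpr)[order], "o-", label=f"AUC = {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="gray", label="no discrimination")
    opt = result.optimal_point
    ax.plot(1 - opt.specificity, opt.sensitivity, "r*", markersize=14,
            label=f"max efficiency @ {opt.cutoff:.2f}")
    ax.set_xlabel("1 - specificity (false alarm rate)")
    ax.set_ylabel("sensitivity (hit rate)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
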