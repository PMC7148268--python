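"""Response/result tables, structured exclusion logging, and the pipeline.

Interchange format is plain CSV (comma, header row, UTF-8, "." decimal) with
JSON-friendly mirrors for programmatic use.  A response table has one row per
(participant, word, presentation):

* category scheme:   participant_id,word,presentation,kind,category,food,intensity
* five-taste scheme: participant_id,word,presentation,kind,sweet,sour,salty,bitter,umami

``kind`` is ``taste`` or ``no_taste``; payload columns are empty on no-taste
rows.  A labels table has one row per participant with the self-report
questionnaire answers (participant_id,initial_answer,followup).

Every word, taste or participant the scorers drop is reported exactly once as
a structured exclusion event with a machine-readable reason code, mirrored to
the ``lgsyn`` logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .category import category_consistency, intensity_consistency
from .domain import (
    TASTES,
    FoodPalette,
    ParticipantRecord,
    PaletteResponse,
    Scheme,
    SelfReport,
    SynStatus,
    TasteProfile,
    UndefinedScoreError,
    ValidationError,
    classify_self_report,
    validate_record,
)
from .roc import LabeledScore, RocResult, classify, roc_analysis
from .simulate import default_cutoff
from .tastes import taste_consistency

__all__ = [
    "ExclusionEvent",
    "PipelineResult",
    "read_responses",
    "write_responses",
    "read_labels",
    "write_labels",
    "run_pipeline",
]

logger = logging.getLogger("lgsyn")

_CAT_COLS = ["participant_id", "word", "presentation", "kind",
             "category", "food", "intensity"]
_FT_COLS = ["participant_id", "word", "presentation", "kind", *TASTES]


@dataclass(frozen=True)
class ExclusionEvent:
    """One dropped word, taste or participant, with a reason code.

    Codes: ``double_no_taste`` (word), ``sparse_taste`` / ``undefined_r2``
    (taste), ``undefined_score`` (participant).
    """

    participant_id: str
    code: str
    item: str  # word id, taste name, or "" for participant-level events
    detail: str = ""

    def log(self) -> None:
        logger.info(
            "exclusion participant=%s code=%s item=%s %s",
            self.participant_id, self.code, self.item, self.detail,
        )


# ---------------------------------------------------------------------------
# Response tables
# ---------------------------------------------------------------------------


def _response_row(pid: str, word: str, pres: int, resp) -> dict:
    row = {"participant_id": pid, "word": word, "presentation": pres,
           "kind": resp.kind}
    if isinstance(resp, PaletteResponse):
        if resp.is_taste:
            row.update(category=resp.category, food=resp.food,
                       intensity=resp.intensity)
    else:
        if resp.is_taste:
            row.update(dict(zip(TASTES, resp.values)))
    return row


def write_responses(
    records: Iterable[ParticipantRecord], path: Union[str, Path]
) -> None:
    """Write participant records as a response CSV (one scheme per file)."""
    records = list(records)
    if not records:
        raise ValidationError("no records to write")
    schemes = {r.scheme for r in records}
    if len(schemes) > 1:
        raise ValidationError("cannot mix schemes in one response table")
    cols = _CAT_COLS if records[0].scheme is Scheme.CATEGORY else _FT_COLS
    rows = [
        _response_row(r.participant_id, word, pres, resp)
        for r in records
        for word in r.words
        for pres, resp in zip((1, 2), r.pair(word))
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _parse_category_row(row: pd.Series) -> PaletteResponse:
    if row["kind"] == "no_taste":
        return PaletteResponse.no_taste()
    return PaletteResponse.taste(
        str(row["category"]), str(row["food"]), float(row["intensity"])
    )


def _parse_five_taste_row(row: pd.Series) -> TasteProfile:
    if row["kind"] == "no_taste":
        return TasteProfile.no_taste()
    return TasteProfile.taste(*(float(row[t]) for t in TASTES))


def read_responses(
    path: Union[str, Path],
    scheme: Scheme | str,
    palette: Optional[FoodPalette] = None,
) -> list[ParticipantRecord]:
    """Read and validate a response CSV into participant records.

    Row-level problems (malformed payloads, duplicate trials, unknown foods,
    a word missing one presentation) are aggregated into one
    :class:`ValidationError` naming the offending CSV lines.
    """
    scheme = Scheme(scheme)
    expected = _CAT_COLS if scheme is Scheme.CATEGORY else _FT_COLS
    df = pd.read_csv(path, dtype={"participant_id": str, "word": str},
                     float_precision="round_trip")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    parse = _parse_category_row if scheme is Scheme.CATEGORY else _parse_five_taste_row
    errors: list[str] = []
    # per participant: word -> {presentation -> response}
    staged: dict[str, dict[str, dict[int, object]]] = {}
    order: dict[str, list[str]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            pid, word, pres = row["participant_id"], row["word"], int(row["presentation"])
            if pres not in (1, 2):
                raise ValidationError(f"presentation must be 1 or 2, got {pres}")
            resp = parse(row)
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        words = staged.setdefault(pid, {})
        if word not in words:
            order.setdefault(pid, []).append(word)
        if pres in words.setdefault(word, {}):
            errors.append(
                f"line {line}: duplicate trial ({pid}, {word}, presentation {pres})"
            )
            continue
        words[word][pres] = resp

    records = []
    for pid, words in staged.items():
        for word, presentations in words.items():
            for p in (1, 2):
                if p not in presentations:
                    errors.append(
                        f"participant {pid}, word {word!r}: missing presentation {p}"
                    )
        if any(len(p) != 2 for p in words.values()):
            continue
        try:
            rec = ParticipantRecord(
                participant_id=pid,
                scheme=scheme,
                words=tuple(order[pid]),
                responses={w: (p[1], p[2]) for w, p in words.items()},
            )
            records.append(validate_record(rec, palette))
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} problem(s):\n  " + "\n  ".join(errors)
        )
    return records


# ---------------------------------------------------------------------------
# Labels tables
# ---------------------------------------------------------------------------


def write_labels(
    labeled: Iterable[tuple[str, SelfReport]], path: Union[str, Path]
) -> None:
    """Write per-participant self-report answers as a labels CSV."""
    rows = [
        {"participant_id": pid, "initial_answer": rep.initial_answer,
         "followup": rep.followup,
         "status": classify_self_report(rep).value}
        for pid, rep in labeled
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path: Union[str, Path]) -> dict[str, SynStatus]:
    """Read a labels CSV to participant -> self-report status."""
    df = pd.read_csv(path, dtype=str)
    for col in ("participant_id", "initial_answer", "followup"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = {}
    for _, row in df.iterrows():
        report = SelfReport(row["initial_answer"], row["followup"])
        out[row["participant_id"]] = classify_self_report(report)
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _exclusion_events(record: ParticipantRecord, result) -> list[ExclusionEvent]:
    events = []
    for word in record.words:
        r1, r2 = record.pair(word)
        if not r1.is_taste and not r2.is_taste:
            events.append(
                ExclusionEvent(record.participant_id, "double_no_taste", word)
            )
    if result is not None and record.scheme is Scheme.FIVE_TASTE:
        for t in result.sparse_tastes:
            events.append(
                ExclusionEvent(record.participant_id, "sparse_taste", t,
                               "assigned on too few words")
            )
        for t in result.undefined_tastes:
            events.append(
                ExclusionEvent(record.participant_id, "undefined_r2", t,
                               "constant vector in a presentation")
            )
    return events


@dataclass
class PipelineResult:
    """Scores, optional ROC evaluation, and the exclusion audit trail."""

    table: pd.DataFrame
    roc: Optional[RocResult]
    exclusions: list[ExclusionEvent]
    cutoff: float


def run_pipeline(
    records: Sequence[ParticipantRecord],
    labels: Optional[Mapping[str, SynStatus]] = None,
    cutoff: Optional[float] = None,
) -> PipelineResult:
    """Score every participant, evaluate ROC against labels, classify.

    Scores each record with its scheme's scorer; participants whose score is
    undefined get a NaN row (with a logged ``undefined_score`` event) and are
    left out of the ROC.  The ROC is computed when labels with both classes
    are available, otherwise skipped; classification always uses ``cutoff``
    (default: the packaged recommended threshold for the scheme — 75.00 for
    category, 26.06 for five-taste).
    """
    if not records:
        raise ValidationError("no records to score")
    schemes = {r.scheme for r in records}
    if len(schemes) > 1:
        raise ValidationError("cannot mix schemes in one pipeline run")
    scheme = records[0].scheme
    if cutoff is None:
        cutoff = default_cutoff(scheme)

    rows, events, scored = [], [], []
    for rec in records:
        status = labels.get(rec.participant_id) if labels else None
        if status is None and rec.self_report is not None:
            status = classify_self_report(rec.self_report)
        row: dict = {"participant_id": rec.participant_id,
                     "status_label": status.value if status else ""}
        try:
            if scheme is Scheme.CATEGORY:
                res = category_consistency(rec)
                row.update(
                    score_percent=res.percent,
                    points_awarded=res.points_awarded,
                    points_available=res.points_available,
                    n_words_scored=res.n_words_scored,
                    n_double_no_taste=res.n_double_no_taste,
                )
                try:
                    row["intensity_r"] = intensity_consistency(rec).r
                except UndefinedScoreError:
                    row["intensity_r"] = np.nan
            else:
                res = taste_consistency(rec)
                row.update(score_percent=res.mean_percent,
                           n_words_used=res.n_words_used,
                           n_double_no_taste=res.n_double_no_taste)
                for t in TASTES:
                    r2 = res.per_taste_r2[t]
                    row[f"r2_{t}"] = np.nan if r2 is None else r2
                    row[f"included_{t}"] = t in res.included_tastes
            events.extend(_exclusion_events(rec, res))
            row["classified_label_at_cutoff"] = classify(row["score_percent"], cutoff)
            if status is not None:
                scored.append(
                    LabeledScore(rec.participant_id, row["score_percent"], status)
                )
        except UndefinedScoreError as exc:
            row.update(score_percent=np.nan, classified_label_at_cutoff="")
            events.extend(_exclusion_events(rec, None))
            events.append(
                ExclusionEvent(rec.participant_id, "undefined_score", "", str(exc))
            )
        rows.append(row)

    for ev in events:
        ev.log()

    roc_result = None
    labels_present = {s.label for s in scored}
    if len(labels_present) == 2:
        roc_result = roc_analysis(scored)
    elif labels:
        logger.info("ROC skipped: need both labels, got %s", sorted(labels_present))

    return PipelineResult(
        table=pd.DataFrame(rows), roc=roc_result,
        exclusions=events, cutoff=float(cutoff),
    )
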