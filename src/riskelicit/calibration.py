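"""Expert calibration against known-answer questions.

Before the risk elicitation proper, each expert answers a set of
calibration questions whose correct answers are known (as intervals).
An expert's response to each question is standardized to a derived
confidence interval, and the score for the question is the proportion
of that derived interval overlapping the correct-answer interval.  The
per-question scores are averaged into a single calibration weight in
[0, 1]; a perfectly calibrated expert weighs 1 and contributes full
height in the downstream aggregation, a poorly calibrated expert less.

Note the score divides by the *expert's* interval width, not the truth
width: a narrow interval wholly inside the truth scores 1.  This is the
deliberate convention of the method (it rewards informative intervals
that land inside the accepted answer) and is kept as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    CredibleInterval,
    ElicitationError,
    ElicitedInterval,
    derive_ci,
)

__all__ = [
    "TruthInterval",
    "CalibrationProfile",
    "question_score",
    "calibrate_expert",
    "calibrate_panel",
    "profiles_to_frames",
]


@dataclass(frozen=True)
class TruthInterval:
    """The pre-determined correct-answer interval for one question.

    A point answer is encoded as a zero-width interval (low == high).
    """

    question_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ElicitationError(
                f"truth interval for {self.question_id!r} out of order or "
                f"outside [0, 1]: ({self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-question overlap scores and the averaged weight for one expert."""

    expert_id: str
    question_scores: Mapping[str, float] = field(default_factory=dict)

    @property
    def weight(self) -> float:
        """Arithmetic mean of the question scores."""
        return calibrate_expert(list(self.question_scores.values()))


def question_score(ci: CredibleInterval, truth: TruthInterval) -> float:
    """Proportion of the expert's derived CI overlapping the truth interval.

    For a positive-width expert interval this is |ci ∩ truth| / |ci|
    with both intervals closed.  Degenerate cases: a zero-width expert
    interval scores 1 if the point lies in the truth interval, else 0;
    a zero-width (point) truth scores 1 if the point lies in the expert
    interval, else 0.
    """
    if ci.width == 0.0:
        return 1.0 if truth.low <= ci.low <= truth.high else 0.0
    if truth.width == 0.0:
        return 1.0 if ci.low <= truth.low <= ci.high else 0.0
    overlap = min(ci.high, truth.high) - max(ci.low, truth.low)
    if overlap <= 0.0:
        return 0.0
    return overlap / ci.width


def calibrate_expert(scores: Sequence[float]) -> float:
    """Average a list of per-question overlap proportions into a weight."""
    if len(scores) == 0:
        raise ElicitationError("cannot calibrate an expert with no scores")
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ElicitationError(f"calibration score outside [0, 1]: {s}")
    return sum(scores) / len(scores)


def calibrate_panel(
    records: Iterable[ElicitedInterval],
    truths: Iterable[TruthInterval],
    target_level: float = 0.8,
    missing: str = "error",
) -> list[CalibrationProfile]:
    """Score every expert's derived intervals against the truth set.

    Parameters
    ----------
    records
        Elicitation records whose ``item_id`` matches a truth
        ``question_id``.
    truths
        Correct-answer intervals, one per calibration question.
    target_level
        Nominal coverage used when deriving each expert's CI.
    missing
        Policy for an expert who did not answer every question:
        ``"error"`` (default) raises; ``"ignore"`` averages over the
        questions the expert did answer.

    Returns
    -------
    list of CalibrationProfile, sorted by expert id.
    """
    if missing not in ("error", "ignore"):
        raise ValueError(f"unknown missing-answer policy: {missing!r}")
    truth_by_q = {t.question_id: t for t in truths}
    if not truth_by_q:
        raise ElicitationError("truth set is empty")

    scores: dict[str, dict[str, float]] = {}
    for rec in records:
        truth = truth_by_q.get(rec.item_id)
        if truth is None:
            # records for non-calibration items are simply not scored
            continue
        ci = derive_ci(rec, target_level)
        scores.setdefault(rec.expert_id, {})[rec.item_id] = question_score(ci, truth)

    if not scores:
        raise ElicitationError("no records matched any calibration question")
    if missing == "error":
        for expert_id, qs in scores.items():
            absent = sorted(set(truth_by_q) - set(qs))
            if absent:
                raise ElicitationError(
                    f"expert {expert_id!r} missing answers for questions {absent}"
                )
    return [
        CalibrationProfile(expert_id, dict(sorted(qs.items())))
        for expert_id, qs in sorted(scores.items())
    ]


def profiles_to_frames(
    profiles: Sequence[CalibrationProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (expert, question, score) and (expert, weight) tables."""
    score_rows = [
        {"expert_id": p.expert_id, "question_id": q, "score": s}
        for p in profiles
        for q, s in p.question_scores.items()
    ]
    weight_rows = [{"expert_id": p.expert_id, "weight": p.weight} for p in profiles]
    return pd.DataFrame(score_rows), pd.DataFrame(weight_rows)
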