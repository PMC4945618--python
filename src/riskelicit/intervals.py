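"""Interval-valued elicitation records and derived confidence intervals.

An expert answers each question by marking a lowest estimate, a best
estimate and a highest estimate on a 0-1 likelihood scale, then states
their confidence (50-100%) that the true value lies inside the interval.
Because experts state different confidences, raw intervals are not
directly comparable; each is rescaled by linear extrapolation about the
best estimate so that all intervals share a common nominal coverage
(80% by default), then clipped to the physical [0, 1] likelihood scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = [
    "ElicitationError",
    "ElicitedInterval",
    "CredibleInterval",
    "validate_record",
    "derive_ci",
]

logger = logging.getLogger(__name__)


class ElicitationError(ValueError):
    """Raised when an elicitation record or derived interval is invalid."""


@dataclass(frozen=True)
class ElicitedInterval:
    """One expert's (low, best, high, confidence) response for one item.

    All four values are decimal fractions: the three estimates are
    likelihoods in [0, 1] with ``low <= best <= high``, and
    ``confidence`` is the expert's stated probability, in [0.5, 1.0],
    that the true value lies inside [low, high].
    """

    expert_id: str
    item_id: str
    low: float
    best: float
    high: float
    confidence: float

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class CredibleInterval:
    """A standardized interval with a common nominal coverage level."""

    low: float
    high: float
    target_level: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ElicitationError(
                f"credible interval out of order or outside [0, 1]: "
                f"({self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low


def validate_record(record: ElicitedInterval) -> ElicitedInterval:
    """Check an elicited record's invariants and return it unchanged.

    Raises
    ------
    ElicitationError
        If the estimates are out of order, outside [0, 1], or the stated
        confidence falls outside the 50-100% protocol range.  The error
        message names the offending expert and item.
    """
    who = f"expert={record.expert_id!r} item={record.item_id!r}"
    if not (0.0 <= record.low and record.high <= 1.0):
        raise ElicitationError(f"estimates outside [0, 1] for {who}")
    if not (record.low <= record.best <= record.high):
        raise ElicitationError(
            f"ordering violation (need low <= best <= high) for {who}: "
            f"({record.low}, {record.best}, {record.high})"
        )
    if not (0.5 <= record.confidence <= 1.0):
        raise ElicitationError(
            f"confidence out of range [0.5, 1.0] for {who}: {record.confidence}"
        )
    return record


def derive_ci(record: ElicitedInterval, target_level: float = 0.8) -> CredibleInterval:
    """Rescale an elicited interval to a derived confidence interval.

    Each side of the interval is stretched (or shrunk) about the best
    estimate by the factor ``target_level / confidence``::

        low'  = best - (best - low)  * target_level / confidence
        high' = best + (high - best) * target_level / confidence

    and the result is clipped to [0, 1].  When the stated confidence
    equals the target level the interval is returned unchanged; higher
    stated confidence shrinks the derived interval (the expert believed
    a narrower region suffices at the target coverage) and lower stated
    confidence widens it.  The derived interval always contains the
    best estimate.

    Parameters
    ----------
    record
        A valid elicitation record (validated here).
    target_level
        Common nominal coverage, in (0, 1]; 0.8 by default.
    """
    validate_record(record)
    if not (0.0 < target_level <= 1.0):
        raise ElicitationError(f"target_level must be in (0, 1]: {target_level}")
    if record.confidence == target_level:
        # scale factor is exactly 1: return the elicited endpoints verbatim
        return CredibleInterval(record.low, record.high, target_level)
    scale = target_level / record.confidence
    low = record.best - (record.best - record.low) * scale
    high = record.best + (record.high - record.best) * scale
    if low < 0.0 or high > 1.0:
        logger.info(
            "clipped derived CI (%g, %g) to [0, 1] for expert=%s item=%s",
            low, high, record.expert_id, record.item_id,
        )
    return CredibleInterval(max(0.0, low), min(1.0, high), target_level)
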