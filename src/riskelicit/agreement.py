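"""Interval agreement aggregation across experts.

The interval agreement approach builds a fuzzy-set-like distribution
from the intervals contributed by a panel: each expert's interval is a
(weight-scaled) indicator function on [0, 1], and the agreement
function is their sum.  Its height at a likelihood x is therefore the
weighted number of experts whose interval contains x — regions where
many experts agree score high, regions covered by a single outlier stay
low, and no distributional assumptions (outlier removal, model fitting)
are imposed.

With ten experts at unit weight, complete agreement tops out at level
10; calibration weighting scales each expert's contribution down to
their calibration weight, so a perfectly calibrated expert still
contributes 1 and a poorly calibrated one less.

The function is represented exactly as a piecewise-constant step
function on the union of all interval endpoints.  Intervals are treated
as closed on both ends, so the level *at* a breakpoint (``point_levels``)
can exceed the level on the adjacent open pieces — e.g. two abutting
intervals [0, .5] and [.5, 1] agree only at the single point 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationProfile
from .intervals import ElicitationError, ElicitedInterval, derive_ci, validate_record

__all__ = [
    "WeightedInterval",
    "AgreementFunction",
    "aggregate",
    "aggregate_variant",
    "VARIANTS",
]

VARIANTS = ("raw", "ci", "calibrated")


@dataclass(frozen=True)
class WeightedInterval:
    """A closed interval [low, high] contributing ``weight`` to agreement."""

    expert_id: str
    low: float
    high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ElicitationError(
                f"interval for {self.expert_id!r} out of order or outside "
                f"[0, 1]: ({self.low}, {self.high})"
            )
        if not (0.0 <= self.weight <= 1.0):
            raise ElicitationError(
                f"weight for {self.expert_id!r} outside [0, 1]: {self.weight}"
            )


class AgreementFunction:
    """Piecewise-constant agreement level as a function of likelihood.

    Attributes
    ----------
    breakpoints : ndarray
        Strictly increasing positions in [0, 1] (the union of all
        interval endpoints).
    levels : ndarray
        Agreement level on each open piece ``(breakpoints[j],
        breakpoints[j+1])``; length ``len(breakpoints) - 1``.
    point_levels : ndarray
        Agreement level at each breakpoint under the closed-endpoint
        convention; always >= the levels of the adjacent pieces.
    n_intervals, total_weight
        Bookkeeping about the aggregated panel.
    """

    def __init__(
        self,
        breakpoints: np.ndarray,
        levels: np.ndarray,
        point_levels: np.ndarray,
        n_intervals: int = 0,
        total_weight: float = np.nan,
    ):
        breakpoints = np.asarray(breakpoints, dtype=float)
        levels = np.asarray(levels, dtype=float)
        point_levels = np.asarray(point_levels, dtype=float)
        if breakpoints.ndim != 1 or breakpoints.size == 0:
            raise ElicitationError("breakpoints must be a non-empty 1-d array")
        if np.any(np.diff(breakpoints) <= 0):
            raise ElicitationError("breakpoints must be strictly increasing")
        if levels.shape != (breakpoints.size - 1,):
            raise ElicitationError("need one piece level per breakpoint gap")
        if point_levels.shape != breakpoints.shape:
            raise ElicitationError("need one point level per breakpoint")
        self.breakpoints = breakpoints
        self.levels = levels
        self.point_levels = point_levels
        self.n_intervals = n_intervals
        self.total_weight = total_weight

    # -- evaluation ----------------------------------------------------

    def __call__(self, x: float) -> float:
        return self.evaluate(x)

    def evaluate(self, x: float) -> float:
        """Agreement level at likelihood ``x`` (closed-endpoint convention)."""
        if not (0.0 <= x <= 1.0):
            raise ElicitationError(f"likelihood outside [0, 1]: {x}")
        bp = self.breakpoints
        j = int(np.searchsorted(bp, x))
        if j < bp.size and bp[j] == x:
            return float(self.point_levels[j])
        if j == 0 or j == bp.size:  # outside the support
            return 0.0
        return float(self.levels[j - 1])

    # -- derived quantities --------------------------------------------

    @property
    def max_level(self) -> float:
        """Global maximum of the function (attained at a breakpoint)."""
        return float(self.point_levels.max())

    @property
    def area(self) -> float:
        """Exact integral of the function over [0, 1]."""
        return float(np.dot(self.levels, np.diff(self.breakpoints)))

    @property
    def support(self) -> tuple[float, float]:
        """Smallest and largest likelihood with positive agreement."""
        pos = self.point_levels > 0.0
        if not pos.any():
            raise ElicitationError("empty agreement: function is identically zero")
        idx = np.nonzero(pos)[0]
        return float(self.breakpoints[idx[0]]), float(self.breakpoints[idx[-1]])

    @property
    def is_empty(self) -> bool:
        return not (self.point_levels > 0.0).any()

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per breakpoint.

        ``level_left`` is the level on the open piece immediately to
        the left of the breakpoint (0 for the first); ``point_level``
        the level at the breakpoint itself.
        """
        level_left = np.concatenate([[0.0], self.levels])
        return pd.DataFrame(
            {
                "breakpoint": self.breakpoints,
                "level_left": level_left,
                "point_level": self.point_levels,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AgreementFunction":
        required = {"breakpoint", "level_left", "point_level"}
        if not required.issubset(frame.columns):
            raise ElicitationError(
                f"agreement table needs columns {sorted(required)}"
            )
        frame = frame.sort_values("breakpoint")
        return cls(
            frame["breakpoint"].to_numpy(dtype=float),
            frame["level_left"].to_numpy(dtype=float)[1:],
            frame["point_level"].to_numpy(dtype=float),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = (self.breakpoints[0], self.breakpoints[-1])
        return (
            f"<AgreementFunction: {self.breakpoints.size} breakpoints on "
            f"[{lo:g}, {hi:g}], max level {self.max_level:g}>"
        )


def aggregate(intervals: Sequence[WeightedInterval]) -> AgreementFunction:
    """Sum weighted interval indicators into an agreement function.

    The representation is exact: breakpoints are the union of all
    interval endpoints, the level on each open piece is the summed
    weight of the intervals covering it, and the level at each
    breakpoint is the summed weight of the (closed) intervals
    containing that point.
    """
    intervals = list(intervals)
    if not intervals:
        raise ElicitationError("cannot aggregate an empty set of intervals")
    lows = np.array([iv.low for iv in intervals])
    highs = np.array([iv.high for iv in intervals])
    weights = np.array([iv.weight for iv in intervals])
    bp = np.unique(np.concatenate([lows, highs]))
    # a closed interval covers the open piece (bp[j], bp[j+1]) iff it
    # spans both endpoints; endpoints are breakpoints, so the test is exact
    covers_piece = (lows[:, None] <= bp[None, :-1]) & (highs[:, None] >= bp[None, 1:])
    levels = weights @ covers_piece if bp.size > 1 else np.empty(0)
    contains_point = (lows[:, None] <= bp[None, :]) & (bp[None, :] <= highs[:, None])
    point_levels = weights @ contains_point
    return AgreementFunction(
        bp,
        levels,
        point_levels,
        n_intervals=len(intervals),
        total_weight=float(weights.sum()),
    )


def aggregate_variant(
    records: Iterable[ElicitedInterval],
    profiles: Sequence[CalibrationProfile] | None = None,
    variant: str = "ci",
    target_level: float = 0.8,
) -> AgreementFunction:
    """Aggregate one item's records under a named estimate variant.

    ``raw``
        Each expert's interval as elicited, unit weight (Raw-estimates).
    ``ci``
        Each interval standardized to the derived CI, unit weight
        (CI-estimates).
    ``calibrated``
        Derived CIs weighted by each expert's calibration weight
        (Calibrated-estimates); requires ``profiles`` covering every
        expert present in ``records``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    weights: dict[str, float] = {}
    if variant == "calibrated":
        if profiles is None:
            raise ElicitationError("calibrated variant requires calibration profiles")
        weights = {p.expert_id: p.weight for p in profiles}

    out: list[WeightedInterval] = []
    for rec in records:
        validate_record(rec)
        if variant == "raw":
            lo, hi, w = rec.low, rec.high, 1.0
        else:
            ci = derive_ci(rec, target_level)
            lo, hi = ci.low, ci.high
            if variant == "ci":
                w = 1.0
            else:
                if rec.expert_id not in weights:
                    raise ElicitationError(
                        f"no calibration profile for expert {rec.expert_id!r}"
                    )
                w = weights[rec.expert_id]
        out.append(WeightedInterval(rec.expert_id, lo, hi, w))
    return aggregate(out)
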