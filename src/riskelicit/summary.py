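"""Crisp likelihood summaries extracted from an agreement function.

Three defuzzification statistics are supported:

``min_max``
    The smallest likelihood attaining the function's global maximum —
    the conservative choice adopted as the default headline statistic,
    since it reports the lowest likelihood at which the panel's
    agreement peaks.
``max_max``
    The largest likelihood attaining the global maximum.
``centroid``
    The centre of gravity of the area under the curve, computed exactly
    piece by piece.

Because intervals are closed, the global maximum is always attained at
a breakpoint (the level at a breakpoint is never below the level of an
adjacent piece), so plateau detection reduces to scanning breakpoint
levels with a relative tolerance of 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import AgreementFunction
from .intervals import ElicitationError

__all__ = ["ItemSummary", "min_max", "max_max", "centroid", "summarize", "STATISTICS"]

STATISTICS = ("min_max", "max_max", "centroid")

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ItemSummary:
    """Bundle of crisp summaries for one aggregated item."""

    item_id: str
    min_max: float
    max_max: float
    centroid: float
    peak_agreement: float
    support_low: float
    support_high: float
    n_experts: int
    headline_statistic: str = "min_max"

    @property
    def headline(self) -> float:
        """Value of the designated headline statistic."""
        return getattr(self, self.headline_statistic)


def _plateau(af: AgreementFunction) -> np.ndarray:
    peak = af.max_level
    if peak <= 0.0:
        raise ElicitationError("empty agreement: function is identically zero")
    hit = af.point_levels >= peak * (1.0 - _REL_TOL)
    return af.breakpoints[hit]


def min_max(af: AgreementFunction) -> float:
    """Smallest likelihood attaining the global maximum agreement."""
    return float(_plateau(af).min())


def max_max(af: AgreementFunction) -> float:
    """Largest likelihood attaining the global maximum agreement."""
    return float(_plateau(af).max())


def centroid(af: AgreementFunction) -> float:
    """Centre of gravity ∫x·af(x)dx / ∫af(x)dx, exact piecewise."""
    area = af.area
    if area <= 0.0:
        raise ElicitationError("centroid undefined: agreement function has zero area")
    b = af.breakpoints
    first_moment = float(np.dot(af.levels, (b[1:] ** 2 - b[:-1] ** 2) / 2.0))
    return first_moment / area


def summarize(
    af: AgreementFunction,
    item_id: str,
    headline_statistic: str = "min_max",
) -> ItemSummary:
    """Compute all summary statistics for one item's agreement function."""
    if headline_statistic not in STATISTICS:
        raise ValueError(
            f"unknown headline statistic {headline_statistic!r}; "
            f"expected one of {STATISTICS}"
        )
    lo, hi = af.support  # raises on identically-zero functions
    return ItemSummary(
        item_id=item_id,
        min_max=min_max(af),
        max_max=max_max(af),
        centroid=centroid(af),
        peak_agreement=af.max_level,
        support_low=lo,
        support_high=hi,
        n_experts=af.n_intervals,
        headline_statistic=headline_statistic,
    )
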