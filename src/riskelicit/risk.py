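"""Risk-factor × biological-element matrix: screening, aggregation, ranking.

The full assessment enumerates every risk-factor × element combination
(e.g. 23 factors × 14 elements = 322 pairs in a wetland-catchment
study).  A preliminary group screening removes combinations judged to
have a 5% or less chance of causing management target failure; the
remaining pairs are each assessed by the expert panel, aggregated, and
summarized.  A factor's importance is reported as the number of
elements for which its headline likelihood exceeds the screening-level
threshold, with the per-pair likelihoods retained for the risk network.

The screening itself is a group judgement, not a computation: it
enters as an input mask, and this module only bookkeeps and validates
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .agreement import aggregate_variant
from .calibration import CalibrationProfile
from .intervals import ElicitationError, ElicitedInterval
from .summary import ItemSummary, summarize

__all__ = [
    "RiskMatrix",
    "RiskReport",
    "pair_id",
    "build_matrix",
    "apply_screening",
    "run_analysis",
    "rank_factors",
]

#: Separator joining a (factor, element) pair into an elicitation item id.
PAIR_SEP = "|"


def pair_id(factor: str, element: str) -> str:
    """Item identifier for a risk-factor × element combination."""
    return f"{factor}{PAIR_SEP}{element}"


@dataclass(frozen=True)
class RiskMatrix:
    """Registry of factor × element pairs with screening status."""

    risk_factors: tuple[str, ...]
    elements: tuple[str, ...]
    retained: frozenset[tuple[str, str]]
    screened_out: frozenset[tuple[str, str]] = frozenset()

    @property
    def n_pairs(self) -> int:
        return len(self.risk_factors) * len(self.elements)

    def __post_init__(self) -> None:
        full = {(f, e) for f in self.risk_factors for e in self.elements}
        if self.retained | self.screened_out != full or (
            self.retained & self.screened_out
        ):
            raise ElicitationError(
                "retained and screened_out must partition the factor × element "
                "cross-product"
            )


@dataclass(frozen=True)
class RiskReport:
    """Per-pair summaries plus per-factor affected-element counts."""

    per_item: tuple[ItemSummary, ...]
    per_factor: Mapping[str, tuple[int, tuple[str, ...]]]
    variant: str
    headline_statistic: str
    headline_threshold: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pair table (one row per retained combination)."""
        rows = []
        for s in self.per_item:
            factor, element = s.item_id.split(PAIR_SEP, 1)
            rows.append(
                {
                    "risk_factor": factor,
                    "element": element,
                    "variant": self.variant,
                    "min_max": s.min_max,
                    "max_max": s.max_max,
                    "centroid": s.centroid,
                    "peak_agreement": s.peak_agreement,
                    "support_low": s.support_low,
                    "support_high": s.support_high,
                    "n_experts": s.n_experts,
                    "headline": s.headline,
                    "affected": s.headline > self.headline_threshold,
                }
            )
        return pd.DataFrame(rows)


def build_matrix(
    factors: Sequence[str], elements: Sequence[str]
) -> RiskMatrix:
    """Enumerate the full factor × element cross-product, all retained."""
    factors = tuple(factors)
    elements = tuple(elements)
    if not factors or not elements:
        raise ElicitationError("factor and element lists must be non-empty")
    if len(set(factors)) != len(factors):
        raise ElicitationError("duplicate risk factors in registry")
    if len(set(elements)) != len(elements):
        raise ElicitationError("duplicate elements in registry")
    retained = frozenset((f, e) for f in factors for e in elements)
    return RiskMatrix(factors, elements, retained)


def apply_screening(
    matrix: RiskMatrix, mask: Iterable[tuple[str, str]]
) -> RiskMatrix:
    """Move the masked pairs (judged ≤ 5% likelihood) to screened-out."""
    mask = frozenset(tuple(p) for p in mask)
    unknown = mask - (matrix.retained | matrix.screened_out)
    if unknown:
        raise ElicitationError(
            f"screening mask references unknown pairs: {sorted(unknown)[:5]}"
        )
    return RiskMatrix(
        matrix.risk_factors,
        matrix.elements,
        retained=matrix.retained - mask,
        screened_out=matrix.screened_out | mask,
    )


def run_analysis(
    matrix: RiskMatrix,
    records: Iterable[ElicitedInterval],
    profiles: Sequence[CalibrationProfile] | None = None,
    variant: str = "calibrated",
    target_level: float = 0.8,
    headline_statistic: str = "min_max",
    headline_threshold: float = 0.05,
) -> RiskReport:
    """Aggregate and summarize every retained pair; count affected elements.

    For each retained (factor, element) pair, the matching records
    (``item_id == pair_id(factor, element)``) are aggregated under the
    chosen variant and summarized.  A factor's affected-element count
    is the number of retained pairs whose headline statistic strictly
    exceeds ``headline_threshold`` (default 0.05, the screening level,
    so sub-threshold results are treated like screened-out pairs).
    """
    by_item: dict[str, list[ElicitedInterval]] = {}
    for rec in records:
        by_item.setdefault(rec.item_id, []).append(rec)

    summaries: list[ItemSummary] = []
    for factor in matrix.risk_factors:
        for element in matrix.elements:
            if (factor, element) not in matrix.retained:
                continue
            item = pair_id(factor, element)
            if item not in by_item:
                raise ElicitationError(
                    f"no elicitation records for retained pair "
                    f"({factor!r}, {element!r})"
                )
            af = aggregate_variant(
                sorted(by_item[item], key=lambda r: r.expert_id),
                profiles,
                variant,
                target_level,
            )
            summaries.append(summarize(af, item, headline_statistic))

    per_factor: dict[str, tuple[int, tuple[str, ...]]] = {}
    for factor in matrix.risk_factors:
        affected = tuple(
            s.item_id.split(PAIR_SEP, 1)[1]
            for s in summaries
            if s.item_id.split(PAIR_SEP, 1)[0] == factor
            and s.headline > headline_threshold
        )
        per_factor[factor] = (len(affected), affected)

    return RiskReport(
        per_item=tuple(summaries),
        per_factor=per_factor,
        variant=variant,
        headline_statistic=headline_statistic,
        headline_threshold=headline_threshold,
    )


def rank_factors(report: RiskReport) -> pd.DataFrame:
    """Order factors by affected-element count, then peak likelihood.

    Sort keys: affected-element count (descending), maximum headline
    likelihood over the factor's retained pairs (descending), then
    factor name (ascending).  The sort is stable.
    """
    if not report.per_item and not report.per_factor:
        raise ElicitationError("cannot rank an empty report")
    max_headline: dict[str, float] = {}
    for s in report.per_item:
        factor = s.item_id.split(PAIR_SEP, 1)[0]
        max_headline[factor] = max(max_headline.get(factor, 0.0), s.headline)
    rows = [
        {
            "risk_factor": factor,
            "n_affected": count,
            "affected_elements": ";".join(elements),
            "max_headline": max_headline.get(factor, 0.0),
        }
        for factor, (count, elements) in report.per_factor.items()
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["n_affected", "max_headline", "risk_factor"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
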