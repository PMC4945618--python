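"""High-level Model/Results interface over the elicitation pipeline.

:class:`IntervalAgreementModel` holds the data of one elicitation
exercise — the panel's interval responses, optionally a calibration
truth set and a risk-factor × element registry with its screening mask
— and :meth:`~IntervalAgreementModel.fit` runs calibration,
aggregation and summarization, returning an
:class:`IntervalAgreementResults` carrying the per-item estimates,
calibration diagnostics and report tables, in the spirit of the
model/results split used by statistical modelling packages.

Example
-------
>>> from riskelicit import IntervalAgreementModel, synthetic
>>> truths, cal, _ = synthetic.generate_truth_set(5, seed=1)
>>> panel = synthetic.generate_panel(
...     synthetic.PanelSpec(true_value=0.7, seed=2), "salinity|waterbirds")
>>> model = IntervalAgreementModel(panel, truths=truths,
...                                calibration_records=cal)
>>> res = model.fit(variant="calibrated")
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import io as rio
from .agreement import AgreementFunction, aggregate_variant
from .calibration import CalibrationProfile, TruthInterval, calibrate_panel
from .intervals import ElicitationError, ElicitedInterval, validate_record
from .risk import (
    RiskMatrix,
    RiskReport,
    apply_screening,
    build_matrix,
    rank_factors,
    run_analysis,
)
from .summary import ItemSummary, summarize

__all__ = ["IntervalAgreementModel", "IntervalAgreementResults"]


class IntervalAgreementModel:
    """Expert-panel elicitation data ready for agreement analysis.

    Parameters
    ----------
    records
        Interval responses for the assessment items.
    truths
        Correct-answer intervals for the calibration questions
        (required for the ``calibrated`` variant unless ``profiles``
        are supplied directly).
    calibration_records
        The panel's responses to the calibration questions.  If
        omitted, ``records`` themselves are matched against the truth
        question ids (useful when both live in one table).
    profiles
        Pre-computed calibration profiles; overrides ``truths``.
    matrix
        Risk-factor × element registry with screening applied.  When
        given, fitting produces a :class:`RiskReport` and factor
        rankings; otherwise only per-item summaries.
    target_level
        Nominal coverage for derived CIs (default 0.8).
    """

    def __init__(
        self,
        records: Iterable[ElicitedInterval],
        truths: Sequence[TruthInterval] | None = None,
        calibration_records: Iterable[ElicitedInterval] | None = None,
        profiles: Sequence[CalibrationProfile] | None = None,
        matrix: RiskMatrix | None = None,
        target_level: float = 0.8,
    ):
        self.records = [validate_record(r) for r in records]
        if not self.records:
            raise ElicitationError("no elicitation records supplied")
        self.truths = list(truths) if truths is not None else None
        self.calibration_records = (
            list(calibration_records) if calibration_records is not None else None
        )
        self.profiles = list(profiles) if profiles is not None else None
        self.matrix = matrix
        self.target_level = target_level

    @classmethod
    def from_csv(
        cls,
        elicitation: str | Path,
        truth: str | Path | None = None,
        calibration_elicitation: str | Path | None = None,
        items: str | Path | None = None,
        screening: str | Path | None = None,
        target_level: float = 0.8,
    ) -> "IntervalAgreementModel":
        """Build a model from the pipeline's CSV schemas."""
        records = rio.read_elicitation(elicitation)
        truths = rio.read_truths(truth) if truth else None
        cal_records = (
            rio.read_elicitation(calibration_elicitation)
            if calibration_elicitation
            else None
        )
        matrix = None
        if items:
            factors, elements = rio.read_items(items)
            matrix = build_matrix(factors, elements)
            if screening:
                matrix = apply_screening(matrix, rio.read_screening(screening))
        return cls(
            records,
            truths=truths,
            calibration_records=cal_records,
            matrix=matrix,
            target_level=target_level,
        )

    def calibrate(self, missing: str = "error") -> list[CalibrationProfile]:
        """Run (or return cached) expert calibration."""
        if self.profiles is not None:
            return self.profiles
        if self.truths is None:
            raise ElicitationError(
                "calibration requires a truth set or precomputed profiles"
            )
        source = (
            self.calibration_records
            if self.calibration_records is not None
            else self.records
        )
        self.profiles = calibrate_panel(
            source, self.truths, self.target_level, missing=missing
        )
        return self.profiles

    def fit(
        self,
        variant: str = "calibrated",
        headline_statistic: str = "min_max",
        headline_threshold: float = 0.05,
    ) -> "IntervalAgreementResults":
        """Aggregate every item and extract its summary statistics."""
        profiles = self.calibrate() if variant == "calibrated" else self.profiles

        by_item: dict[str, list[ElicitedInterval]] = {}
        for rec in self.records:
            by_item.setdefault(rec.item_id, []).append(rec)

        functions: dict[str, AgreementFunction] = {}
        summaries: list[ItemSummary] = []
        report = None
        if self.matrix is not None:
            report = run_analysis(
                self.matrix,
                self.records,
                profiles,
                variant=variant,
                target_level=self.target_level,
                headline_statistic=headline_statistic,
                headline_threshold=headline_threshold,
            )
        for item, recs in sorted(by_item.items()):
            af = aggregate_variant(
                sorted(recs, key=lambda r: r.expert_id),
                profiles,
                variant,
                self.target_level,
            )
            functions[item] = af
            summaries.append(summarize(af, item, headline_statistic))

        return IntervalAgreementResults(
            model=self,
            variant=variant,
            profiles=profiles,
            functions=functions,
            item_summaries=summaries,
            report=report,
            headline_statistic=headline_statistic,
            headline_threshold=headline_threshold,
        )


class IntervalAgreementResults:
    """Fitted estimates, diagnostics and report tables.

    Attributes
    ----------
    functions
        Mapping item id → :class:`AgreementFunction`.
    item_summaries
        One :class:`ItemSummary` per item (min-max, max-max, centroid,
        peak agreement, support).
    calibration_weights
        Per-expert weights as a pandas Series (empty when the fit did
        not use calibration).
    report
        :class:`RiskReport` when the model carries a risk matrix.
    """

    def __init__(
        self,
        model: IntervalAgreementModel,
        variant: str,
        profiles: Sequence[CalibrationProfile] | None,
        functions: dict[str, AgreementFunction],
        item_summaries: Sequence[ItemSummary],
        report: RiskReport | None,
        headline_statistic: str,
        headline_threshold: float,
    ):
        self.model = model
        self.variant = variant
        self.profiles = list(profiles) if profiles is not None else None
        self.functions = functions
        self.item_summaries = list(item_summaries)
        self.report = report
        self.headline_statistic = headline_statistic
        self.headline_threshold = headline_threshold

    @property
    def calibration_weights(self) -> pd.Series:
        if not self.profiles:
            return pd.Series(dtype=float, name="weight")
        return pd.Series(
            {p.expert_id: p.weight for p in self.profiles}, name="weight"
        ).sort_index()

    @property
    def summaries(self) -> pd.DataFrame:
        """Per-item summary statistics as a tidy DataFrame."""
        return pd.DataFrame(
            [
                {
                    "item_id": s.item_id,
                    "min_max": s.min_max,
                    "max_max": s.max_max,
                    "centroid": s.centroid,
                    "peak_agreement": s.peak_agreement,
                    "support_low": s.support_low,
                    "support_high": s.support_high,
                    "n_experts": s.n_experts,
                }
                for s in self.item_summaries
            ]
        )

    def rank_factors(self) -> pd.DataFrame:
        if self.report is None:
            raise ElicitationError(
                "factor ranking requires a risk matrix on the model"
            )
        return rank_factors(self.report)

    def plot_agreement(self, item_id: str, path=None, ax=None):
        from .plotting import plot_agreement

        if item_id not in self.functions:
            raise KeyError(item_id)
        return plot_agreement(self.functions[item_id], path=path, title=item_id, ax=ax)

    def plot_network(self, path=None, ax=None):
        from .plotting import plot_risk_network

        if self.report is None:
            raise ElicitationError("network plot requires a risk matrix on the model")
        return plot_risk_network(self.report, path=path, ax=ax)

    def summary(self) -> str:
        """Human-readable report of weights, estimates and rankings."""
        lines = [
            "Interval agreement elicitation results",
            "=" * 46,
            f"variant: {self.variant}    "
            f"target CI level: {self.model.target_level:.0%}",
            f"headline statistic: {self.headline_statistic} "
            f"(threshold {self.headline_threshold:g})",
            f"items: {len(self.item_summaries)}",
        ]
        if self.profiles:
            w = self.calibration_weights
            lines += [
                "",
                f"Calibration weights ({len(w)} experts): "
                f"mean={w.mean():.2f}, range={w.min():.2f} to {w.max():.2f}",
            ]
        lines += ["", "Per-item estimates:", self.summaries.round(4).to_string(index=False)]
        if self.report is not None:
            lines += [
                "",
                "Risk-factor ranking (affected elements above threshold):",
                self.rank_factors().round(4).to_string(index=False),
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<IntervalAgreementResults: {len(self.item_summaries)} items, "
            f"variant={self.variant!r}>"
        )
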