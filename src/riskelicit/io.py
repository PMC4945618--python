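"""CSV schemas, validated loaders/writers, and run configuration.

All likelihoods and confidences are stored as decimal fractions, never
percentages; loaders reject values above 1 with a hint to convert
units.  Every schema round-trips: writing a table and reading it back
reproduces the records exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .agreement import VARIANTS
from .calibration import CalibrationProfile, TruthInterval, profiles_to_frames
from .intervals import ElicitationError, ElicitedInterval, validate_record
from .summary import STATISTICS, ItemSummary

__all__ = [
    "RunConfig",
    "read_elicitation",
    "write_elicitation",
    "read_truths",
    "write_truths",
    "read_items",
    "write_items",
    "read_screening",
    "write_screening",
    "read_calibration_weights",
    "write_calibration",
    "write_summaries",
]

ELICITATION_COLUMNS = ["expert_id", "item_id", "low", "best", "high", "confidence"]
TRUTH_COLUMNS = ["question_id", "low", "high"]
ITEM_COLUMNS = ["risk_factor", "element"]
SCREENING_COLUMNS = ["risk_factor", "element", "retained"]


@dataclass
class RunConfig:
    """Pipeline configuration; every random draw flows from ``seed``."""

    target_level: float = 0.80
    variant: str = "calibrated"
    headline_statistic: str = "min_max"
    headline_threshold: float = 0.05
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self) -> None:
        if not (0.0 < self.target_level <= 1.0):
            raise ValueError(f"target_level must be in (0, 1]: {self.target_level}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}: {self.variant!r}")
        if self.headline_statistic not in STATISTICS:
            raise ValueError(
                f"headline_statistic must be one of {STATISTICS}: "
                f"{self.headline_statistic!r}"
            )
        if not (0.0 <= self.headline_threshold <= 1.0):
            raise ValueError(
                f"headline_threshold must be in [0, 1]: {self.headline_threshold}"
            )
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a key/value config file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = set(columns) - set(frame.columns)
    if missing:
        raise ElicitationError(
            f"{path}: missing required columns {sorted(missing)} "
            f"(found {list(frame.columns)})"
        )
    extra = set(frame.columns) - set(columns)
    if extra:
        raise ElicitationError(f"{path}: unknown columns {sorted(extra)}")
    return frame


def _check_fraction(path: Path | str, line: int, name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        hint = (
            " (values look like percentages; divide by 100)" if value > 1.0 else ""
        )
        raise ElicitationError(
            f"{path}, line {line}: {name}={value} outside [0, 1]{hint}"
        )


def read_elicitation(path: str | Path) -> list[ElicitedInterval]:
    """Load and validate ``expert_id,item_id,low,best,high,confidence``."""
    frame = _read_csv(path, ELICITATION_COLUMNS)
    records = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        for name in ("low", "best", "high", "confidence"):
            _check_fraction(path, line, name, float(row[name]))
        try:
            records.append(
                validate_record(
                    ElicitedInterval(
                        expert_id=str(row["expert_id"]),
                        item_id=str(row["item_id"]),
                        low=float(row["low"]),
                        best=float(row["best"]),
                        high=float(row["high"]),
                        confidence=float(row["confidence"]),
                    )
                )
            )
        except ElicitationError as err:
            raise ElicitationError(f"{path}, line {line}: {err}") from err
    return records


def write_elicitation(records: Iterable[ElicitedInterval], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "expert_id": r.expert_id,
                "item_id": r.item_id,
                "low": r.low,
                "best": r.best,
                "high": r.high,
                "confidence": r.confidence,
            }
            for r in records
        ],
        columns=ELICITATION_COLUMNS,
    ).to_csv(path, index=False)


def read_truths(path: str | Path) -> list[TruthInterval]:
    """Load ``question_id,low,high`` correct-answer intervals."""
    frame = _read_csv(path, TRUTH_COLUMNS)
    truths = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        for name in ("low", "high"):
            _check_fraction(path, line, name, float(row[name]))
        try:
            truths.append(
                TruthInterval(str(row["question_id"]), float(row["low"]), float(row["high"]))
            )
        except ElicitationError as err:
            raise ElicitationError(f"{path}, line {line}: {err}") from err
    return truths


def write_truths(truths: Iterable[TruthInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"question_id": t.question_id, "low": t.low, "high": t.high} for t in truths],
        columns=TRUTH_COLUMNS,
    ).to_csv(path, index=False)


def read_items(path: str | Path) -> tuple[list[str], list[str]]:
    """Load the ``risk_factor,element`` registry; returns unique ordered lists."""
    frame = _read_csv(path, ITEM_COLUMNS)
    factors = list(dict.fromkeys(frame["risk_factor"].astype(str)))
    elements = list(dict.fromkeys(frame["element"].astype(str)))
    return factors, elements


def write_items(factors: Sequence[str], elements: Sequence[str], path: str | Path) -> None:
    rows = [{"risk_factor": f, "element": e} for f in factors for e in elements]
    pd.DataFrame(rows, columns=ITEM_COLUMNS).to_csv(path, index=False)


def read_screening(path: str | Path) -> set[tuple[str, str]]:
    """Load the screening file; returns the *mask* of screened-out pairs."""
    frame = _read_csv(path, SCREENING_COLUMNS)
    mask = set()
    for idx, row in frame.iterrows():
        retained = row["retained"]
        if isinstance(retained, str):
            token = retained.strip().lower()
            if token not in ("true", "false", "0", "1"):
                raise ElicitationError(
                    f"{path}, line {int(idx) + 2}: retained must be boolean, "
                    f"got {retained!r}"
                )
            retained = token in ("true", "1")
        if not bool(retained):
            mask.add((str(row["risk_factor"]), str(row["element"])))
    return mask


def write_screening(
    retained: Iterable[tuple[str, str]],
    screened_out: Iterable[tuple[str, str]],
    path: str | Path,
) -> None:
    rows = [
        {"risk_factor": f, "element": e, "retained": keep}
        for keep, pairs in ((True, retained), (False, screened_out))
        for f, e in sorted(pairs)
    ]
    pd.DataFrame(rows, columns=SCREENING_COLUMNS).to_csv(path, index=False)


def write_calibration(
    profiles: Sequence[CalibrationProfile],
    scores_path: str | Path,
    weights_path: str | Path,
) -> None:
    scores, weights = profiles_to_frames(profiles)
    scores.to_csv(scores_path, index=False)
    weights.to_csv(weights_path, index=False)


def read_calibration_weights(path: str | Path) -> list[CalibrationProfile]:
    """Load ``expert_id,weight`` as single-score profiles.

    A profile re-read this way carries its weight as one pseudo-score,
    which preserves the weight exactly.
    """
    frame = _read_csv(path, ["expert_id", "weight"])
    profiles = []
    for idx, row in frame.iterrows():
        _check_fraction(path, int(idx) + 2, "weight", float(row["weight"]))
        profiles.append(
            CalibrationProfile(str(row["expert_id"]), {"_weight": float(row["weight"])})
        )
    return profiles


def write_summaries(
    summaries: Iterable[ItemSummary], variant: str, path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "item_id": s.item_id,
                "variant": variant,
                "min_max": s.min_max,
                "max_max": s.max_max,
                "centroid": s.centroid,
                "peak_agreement": s.peak_agreement,
                "support_low": s.support_low,
                "support_high": s.support_high,
                "n_experts": s.n_experts,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)
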