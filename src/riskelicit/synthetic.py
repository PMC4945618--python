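"""Reproducible synthetic expert panels and calibration truth sets.

Two kinds of fixtures are generated:

* *Behavioural panels* (:func:`generate_panel`,
  :func:`generate_calibration_exercise`): each simulated expert holds a
  normal belief about the true value, draws a best estimate from it,
  and reports an interval whose half-width corresponds to a coverage
  level; an *honest* expert's stated confidence equals that coverage,
  an *overconfident* expert reports an interval too narrow for the
  confidence they state, an *underconfident* one too wide.  These
  panels exercise the full pipeline statistically.

* *Constructed truth sets* (:func:`generate_truth_set`): responses are
  built backwards from prescribed overlap proportions with the truth
  intervals, so the calibration weights that the pipeline should
  recover are known exactly.  All endpoints and overlaps are multiples
  of 1/64, which keeps every arithmetic step exact in binary floating
  point and makes exact-recovery assertions meaningful.

The distributional choices are fixture conventions, not claims about
real experts; everything is parameterized and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .calibration import TruthInterval
from .intervals import ElicitedInterval

__all__ = [
    "PanelSpec",
    "generate_panel",
    "generate_truth_set",
    "generate_calibration_exercise",
    "BEHAVIOURS",
]

BEHAVIOURS = ("honest", "overconfident", "underconfident")

#: Coverage cap: a stated confidence of 1.0 would give an infinite
#: normal quantile, so half-widths are computed at min(c, _MAX_COVERAGE).
_MAX_COVERAGE = 0.995

#: How far (in coverage) over/underconfident experts' actual interval
#: coverage sits from the confidence they state.
_COVERAGE_GAP = 0.3


@dataclass(frozen=True)
class PanelSpec:
    """Parameters for one synthetic panel answering one item.

    Parameters
    ----------
    n_experts
        Panel size; the study protocol used ten.
    true_value
        The latent likelihood the panel is estimating, in [0, 1].
    bias
        Systematic offset of expert best estimates from the truth;
        scalar or one value per expert.  Default 0.
    spread
        Standard deviation of each expert's belief about the truth (and
        hence the scale of their interval half-widths); scalar or per
        expert.  Default 0.1 — a moderately informative panel on a 0-1
        likelihood scale.
    confidence_behaviour
        ``"honest"`` (stated confidence equals the interval's nominal
        coverage), ``"overconfident"`` or ``"underconfident"``.
    seed
        Fixes every draw.
    """

    n_experts: int = 10
    true_value: float = 0.5
    bias: float | Sequence[float] = 0.0
    spread: float | Sequence[float] = 0.1
    confidence_behaviour: str = "honest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if not (0.0 <= self.true_value <= 1.0):
            raise ValueError("true_value must lie in [0, 1]")
        if self.confidence_behaviour not in BEHAVIOURS:
            raise ValueError(
                f"confidence_behaviour must be one of {BEHAVIOURS}"
            )


def _per_expert(value: float | Sequence[float], n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,))
    return np.array(arr)


def generate_panel(spec: PanelSpec, item_id: str) -> list[ElicitedInterval]:
    """Draw one panel's interval responses for a single item.

    Per expert: the best estimate is drawn from N(true_value + bias,
    spread) and clipped to [0, 1]; a stated confidence is drawn
    uniformly on [0.5, 1.0]; the interval half-width is
    ``spread * z((1 + coverage) / 2)`` where coverage equals the stated
    confidence for honest experts and is shifted down (up) by 0.3 for
    overconfident (underconfident) ones; endpoints are clipped to
    [0, 1].  With ``spread -> 0`` all intervals collapse onto the true
    value.
    """
    rng = np.random.default_rng(spec.seed)
    bias = _per_expert(spec.bias, spec.n_experts)
    spread = _per_expert(spec.spread, spec.n_experts)

    records = []
    for i in range(spec.n_experts):
        best = float(np.clip(rng.normal(spec.true_value + bias[i], spread[i]), 0, 1))
        stated = float(rng.uniform(0.5, 1.0))
        if spec.confidence_behaviour == "honest":
            coverage = stated
        elif spec.confidence_behaviour == "overconfident":
            coverage = max(0.1, stated - _COVERAGE_GAP)
        else:
            coverage = stated + _COVERAGE_GAP
        half = spread[i] * norm.ppf((1.0 + min(coverage, _MAX_COVERAGE)) / 2.0)
        records.append(
            ElicitedInterval(
                expert_id=f"E{i + 1:02d}",
                item_id=item_id,
                low=float(np.clip(best - half, 0, best)),
                best=best,
                high=float(np.clip(best + half, best, 1)),
                confidence=stated,
            )
        )
    return records


def _grid64(rng: np.random.Generator, lo: float, hi: float) -> float:
    """A uniform draw from the multiples of 1/64 inside [lo, hi]."""
    k_lo = int(np.ceil(lo * 64))
    k_hi = int(np.floor(hi * 64))
    return int(rng.integers(k_lo, k_hi + 1)) / 64.0


def generate_truth_set(
    n_questions: int,
    difficulty: float = 0.25,
    seed: int = 0,
    n_experts: int = 10,
    overlaps: np.ndarray | None = None,
    target_level: float = 0.8,
) -> tuple[list[TruthInterval], list[ElicitedInterval], dict[str, float]]:
    """Build a truth set plus responses with prescribed overlap scores.

    Each question's truth interval has width ``difficulty`` (a multiple
    of 1/64 after snapping).  For expert *e* and question *q* the
    response interval is placed so that exactly the prescribed fraction
    ``overlaps[e, q]`` of it lies inside the truth interval; stated
    confidence equals ``target_level``, so the derived CI is the raw
    interval and the calibration pipeline must recover the weight
    ``mean_q overlaps[e, q]`` exactly.

    Parameters
    ----------
    overlaps
        Optional (n_experts, n_questions) array of overlap fractions;
        values are snapped to multiples of 1/64.  Drawn uniformly from
        that grid if omitted.

    Returns
    -------
    (truths, records, expected_weights)
        ``expected_weights`` maps expert id to the exact weight that
        calibration should recover.
    """
    if n_questions < 1:
        raise ValueError("n_questions must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(1, round(difficulty * 64)) / 64.0
    # response intervals are half the truth width: narrow enough that any
    # overlap fraction can be realised by sliding across the upper edge
    resp_w = max(1, round(width * 64 / 2)) / 64.0

    if overlaps is None:
        overlaps = rng.integers(0, 65, size=(n_experts, n_questions)) / 64.0
    else:
        overlaps = np.asarray(overlaps, dtype=float)
        if overlaps.shape != (n_experts, n_questions):
            raise ValueError(
                f"overlaps must have shape {(n_experts, n_questions)}"
            )
        overlaps = np.round(overlaps * 64) / 64.0

    truths: list[TruthInterval] = []
    records: list[ElicitedInterval] = []
    for q in range(n_questions):
        # keep the truth away from the edges so responses never clip
        t_lo = _grid64(rng, resp_w + 1 / 64, 1.0 - width - resp_w - 1 / 64)
        t_hi = t_lo + width
        qid = f"Q{q + 1:02d}"
        truths.append(TruthInterval(qid, t_lo, t_hi))
        for e in range(n_experts):
            p = overlaps[e, q]
            if p == 0.0:
                lo = t_hi + 1 / 64.0  # fully outside, just above
            else:
                lo = t_hi - p * resp_w  # overlap = p * resp_w exactly
            hi = lo + resp_w
            records.append(
                ElicitedInterval(
                    expert_id=f"E{e + 1:02d}",
                    item_id=qid,
                    low=lo,
                    best=(lo + hi) / 2.0,
                    high=hi,
                    confidence=target_level,
                )
            )
    # same summation order as calibrate_expert, so recovery is bit-exact
    expected = {
        f"E{e + 1:02d}": sum(overlaps[e].tolist()) / n_questions
        for e in range(n_experts)
    }
    return truths, records, expected


def generate_calibration_exercise(
    n_questions: int = 5,
    n_experts: int = 10,
    truth_width: float = 0.0,
    spread: float = 0.1,
    confidence_behaviour: str = "honest",
    seed: int = 0,
) -> tuple[list[TruthInterval], list[ElicitedInterval]]:
    """Simulate a behavioural calibration exercise.

    Each question has a latent true value; the truth interval is the
    true value ± ``truth_width / 2`` (clipped to [0, 1]) and the panel
    answers via :func:`generate_panel`.  Unlike
    :func:`generate_truth_set` the resulting calibration weights are
    not prescribed — this fixture is for statistical behaviour (e.g.
    overconfident panels scoring worse than honest ones).

    By default the correct answers are points (zero-width truths), the
    natural encoding for factual calibration questions whose answer is
    a single value; an expert's score on a question is then membership
    of the truth in their derived CI, so an honest expert's expected
    score is their interval's actual coverage while an overconfident
    expert's too-narrow intervals miss more often.  Note that with the
    overlap-proportion scoring rule and *positive*-width truths,
    narrower intervals are weakly favoured in expectation, so wide
    truths do not discriminate against overconfidence.
    """
    rng = np.random.default_rng(seed)
    truths: list[TruthInterval] = []
    records: list[ElicitedInterval] = []
    for q in range(n_questions):
        true_value = float(rng.uniform(0.2, 0.8))
        qid = f"Q{q + 1:02d}"
        truths.append(
            TruthInterval(
                qid,
                max(0.0, true_value - truth_width / 2),
                min(1.0, true_value + truth_width / 2),
            )
        )
        panel_seed = int(rng.integers(0, 2**31 - 1))
        spec = PanelSpec(
            n_experts=n_experts,
            true_value=true_value,
            spread=spread,
            confidence_behaviour=confidence_behaviour,
            seed=panel_seed,
        )
        records.extend(generate_panel(spec, qid))
    return truths, records
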