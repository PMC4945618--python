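"""Shared fixtures: small hand-built panels and a toy risk study."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from riskelicit import (
    CalibrationProfile,
    ElicitedInterval,
    WeightedInterval,
    aggregate,
    apply_screening,
    build_matrix,
    pair_id,
)


@pytest.fixture
def two_interval_af():
    """Unit-weight intervals (0, 0.4) and (0.2, 0.6): the worked example."""
    return aggregate(
        [WeightedInterval("a", 0.0, 0.4), WeightedInterval("b", 0.2, 0.6)]
    )


@pytest.fixture
def bimodal_af():
    """Two pairs of agreeing intervals at opposite ends of the scale."""
    return aggregate(
        [
            WeightedInterval("a", 0.1, 0.2),
            WeightedInterval("b", 0.1, 0.2),
            WeightedInterval("c", 0.7, 0.8),
            WeightedInterval("d", 0.7, 0.8),
        ]
    )


def consensus_panel(item_id, low, best, high, n=10, confidence=0.8):
    """A panel of n experts giving identical interval responses."""
    return [
        ElicitedInterval(f"E{i + 1:02d}", item_id, low, best, high, confidence)
        for i in range(n)
    ]


@pytest.fixture
def toy_study():
    """A 2x2 factor x element study with constructed affected counts.

    Three retained pairs (one screened out).  Panels are built so the
    min-max headline is known by construction: the salinity/waterbirds
    pair peaks at 0.6, drought/waterbirds at 0.2, and the
    salinity/shrubland panel agrees the likelihood is negligible
    (min-max 0.0, below the 5% threshold).  Expected affected counts:
    salinity 1, drought 1.
    """
    factors = ["salinity", "drought"]
    elements = ["waterbirds", "shrubland"]
    matrix = apply_screening(
        build_matrix(factors, elements), {("drought", "shrubland")}
    )
    records = (
        consensus_panel(pair_id("salinity", "waterbirds"), 0.6, 0.7, 0.8)
        + consensus_panel(pair_id("drought", "waterbirds"), 0.2, 0.3, 0.4)
        + consensus_panel(pair_id("salinity", "shrubland"), 0.0, 0.01, 0.02)
    )
    profiles = [CalibrationProfile(f"E{i + 1:02d}", {"Q1": 1.0}) for i in range(10)]
    expected_counts = {"salinity": 1, "drought": 1}
    return matrix, records, profiles, expected_counts


def brute_force_level(intervals, x):
    """Independent oracle: weighted count of closed intervals covering x."""
    return sum(iv.weight for iv in intervals if iv.low <= x <= iv.high)


@pytest.fixture
def rng():
    return np.random.default_rng(987654)
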