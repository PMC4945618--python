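"""Interval agreement aggregation against an independent grid oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_level
from riskelicit import (
    AgreementFunction,
    CalibrationProfile,
    ElicitationError,
    ElicitedInterval,
    WeightedInterval,
    aggregate,
    aggregate_variant,
)


@st.composite
def weighted_panels(draw, max_size=12):
    n = draw(st.integers(1, max_size))
    out = []
    for i in range(n):
        lo = draw(st.floats(0, 1))
        hi = draw(st.floats(lo, 1))
        w = draw(st.floats(0, 1))
        out.append(WeightedInterval(f"E{i:02d}", lo, hi, w))
    return out


class TestAggregate:
    def test_ten_identical_unit_intervals_peak_at_ten(self):
        afn = aggregate([WeightedInterval(str(i), 0.3, 0.5) for i in range(10)])
        assert afn.max_level == 10.0
        assert afn.evaluate(0.4) == 10.0
        assert afn.evaluate(0.2) == 0.0

    def test_single_interval_is_an_indicator(self):
        afn = aggregate([WeightedInterval("a", 0.2, 0.6)])
        assert afn.evaluate(0.2) == 1.0  # closed left endpoint
        assert afn.evaluate(0.4) == 1.0
        assert afn.evaluate(0.6) == 1.0
        assert afn.evaluate(0.1) == 0.0
        assert afn.evaluate(0.9) == 0.0

    def test_two_overlapping_intervals_step_levels(self, two_interval_af):
        for x, expected in [
            (0.0, 1.0), (0.1, 1.0), (0.2, 2.0), (0.3, 2.0),
            (0.4, 2.0), (0.5, 1.0), (0.6, 1.0), (0.7, 0.0),
        ]:
            assert two_interval_af.evaluate(x) == expected

    def test_abutting_intervals_agree_only_at_the_shared_point(self):
        afn = aggregate(
            [WeightedInterval("a", 0.0, 0.5), WeightedInterval("b", 0.5, 1.0)]
        )
        assert afn.evaluate(0.5) == 2.0
        assert afn.evaluate(0.49) == 1.0
        assert afn.evaluate(0.51) == 1.0
        assert afn.max_level == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ElicitationError):
            aggregate([])

    def test_evaluate_outside_unit_interval_rejected(self, two_interval_af):
        with pytest.raises(ElicitationError):
            two_interval_af.evaluate(-0.1)
        with pytest.raises(ElicitationError):
            two_interval_af.evaluate(1.5)

    def test_zero_width_interval_contributes_a_point_mass(self):
        afn = aggregate([WeightedInterval("a", 0.5, 0.5)])
        assert afn.evaluate(0.5) == 1.0
        assert afn.area == 0.0

    @given(weighted_panels())
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_count_on_a_grid(self, panel):
        """Exact representation agrees with the covering-count oracle."""
        afn = aggregate(panel)
        for x in np.arange(0.0, 1.0001, 1e-3):
            x = float(round(x, 3))
            assert afn.evaluate(x) == pytest.approx(
                brute_force_level(panel, x), abs=1e-12
            )

    @given(weighted_panels())
    @settings(max_examples=200, deadline=None)
    def test_area_equals_sum_of_weighted_widths(self, panel):
        afn = aggregate(panel)
        expected = sum(iv.weight * (iv.high - iv.low) for iv in panel)
        assert afn.area == pytest.approx(expected, abs=1e-12)

    @given(weighted_panels(), st.data())
    @settings(max_examples=100, deadline=None)
    def test_enlarging_an_interval_never_lowers_the_level(self, panel, data):
        i = data.draw(st.integers(0, len(panel) - 1))
        iv = panel[i]
        bigger = WeightedInterval(
            iv.expert_id,
            data.draw(st.floats(0, iv.low)),
            data.draw(st.floats(iv.high, 1)),
            iv.weight,
        )
        before = aggregate(panel)
        after = aggregate(panel[:i] + [bigger] + panel[i + 1 :])
        for x in np.linspace(0, 1, 101):
            assert after.evaluate(float(x)) >= before.evaluate(float(x)) - 1e-12

    @given(weighted_panels())
    @settings(max_examples=200, deadline=None)
    def test_peak_reaches_total_weight_iff_common_point(self, panel):
        """The peak hits the summed weights iff all contributing intervals meet.

        Weights below 0.05 are zeroed so the strict-inequality branch
        is not confounded by floating-point noise.
        """
        panel = [
            WeightedInterval(
                iv.expert_id, iv.low, iv.high,
                0.0 if iv.weight < 0.05 else iv.weight,
            )
            for iv in panel
        ]
        pos = [iv for iv in panel if iv.weight > 0]
        afn = aggregate(panel)
        total = sum(iv.weight for iv in panel)
        if not pos:
            assert afn.max_level == 0.0
        elif max(iv.low for iv in pos) <= min(iv.high for iv in pos):
            assert afn.max_level == pytest.approx(total, abs=1e-12)
        else:
            assert afn.max_level < total - 1e-12

    def test_round_trip_through_frame(self, two_interval_af):
        back = AgreementFunction.from_frame(two_interval_af.to_frame())
        np.testing.assert_array_equal(back.breakpoints, two_interval_af.breakpoints)
        np.testing.assert_array_equal(back.levels, two_interval_af.levels)
        np.testing.assert_array_equal(back.point_levels, two_interval_af.point_levels)


def consensus(item, low, best, high, n=10, conf=0.8, experts=None):
    ids = experts or [f"E{i + 1:02d}" for i in range(n)]
    return [ElicitedInterval(e, item, low, best, high, conf) for e in ids]


class TestAggregateVariant:
    def test_raw_equals_ci_when_confidence_matches_target(self):
        records = consensus("it", 0.2, 0.4, 0.6, n=3, conf=0.8)
        raw = aggregate_variant(records, variant="raw")
        ci = aggregate_variant(records, variant="ci", target_level=0.8)
        np.testing.assert_array_equal(raw.breakpoints, ci.breakpoints)
        np.testing.assert_array_equal(raw.levels, ci.levels)

    def test_ci_variant_uses_derived_endpoints(self):
        records = [ElicitedInterval("E01", "it", 0.2, 0.4, 0.6, 1.0)]
        afn = aggregate_variant(records, variant="ci", target_level=0.8)
        assert afn.breakpoints[0] == pytest.approx(0.24)
        assert afn.breakpoints[-1] == pytest.approx(0.56)

    def test_calibration_weight_scales_the_contribution(self):
        records = consensus("it", 0.2, 0.4, 0.6, n=1)
        profiles = [CalibrationProfile("E01", {"Q1": 0.5})]
        afn = aggregate_variant(records, profiles, variant="calibrated")
        assert afn.max_level == 0.5

    def test_ten_perfectly_calibrated_experts_peak_at_ten(self):
        records = consensus("it", 0.3, 0.4, 0.5, n=10)
        profiles = [
            CalibrationProfile(f"E{i + 1:02d}", {"Q1": 1.0}) for i in range(10)
        ]
        afn = aggregate_variant(records, profiles, variant="calibrated")
        assert afn.max_level == 10.0

    def test_calibrated_variant_requires_full_profiles(self):
        records = consensus("it", 0.2, 0.4, 0.6, n=2)
        with pytest.raises(ElicitationError, match="profile"):
            aggregate_variant(records, None, variant="calibrated")
        with pytest.raises(ElicitationError, match="E02"):
            aggregate_variant(
                records, [CalibrationProfile("E01", {"Q1": 1.0})], variant="calibrated"
            )

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            aggregate_variant(consensus("it", 0.2, 0.4, 0.6, n=1), variant="mean")
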