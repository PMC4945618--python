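"""Overlap scoring and per-expert calibration weights."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskelicit import (
    CredibleInterval,
    ElicitationError,
    ElicitedInterval,
    TruthInterval,
    calibrate_expert,
    calibrate_panel,
    question_score,
)
from riskelicit.calibration import profiles_to_frames


def ci(low, high):
    return CredibleInterval(low, high)


def truth(low, high, qid="Q01"):
    return TruthInterval(qid, low, high)


class TestQuestionScore:
    @pytest.mark.parametrize(
        "expert, correct, expected",
        [
            ((0.2, 0.4), (0.2, 0.4), 1.0),   # full overlap
            ((0.2, 0.6), (0.3, 0.5), 0.5),   # half of the expert interval
            ((0.0, 0.1), (0.5, 0.6), 0.0),   # disjoint
            ((0.3, 0.5), (0.2, 0.6), 1.0),   # expert interval inside truth
            ((0.2, 0.6), (0.4, 0.8), 0.5),   # partial, right side
        ],
    )
    def test_overlap_proportion(self, expert, correct, expected):
        assert question_score(ci(*expert), truth(*correct)) == pytest.approx(expected)

    def test_zero_width_expert_interval_scores_by_membership(self):
        assert question_score(ci(0.3, 0.3), truth(0.2, 0.4)) == 1.0
        assert question_score(ci(0.5, 0.5), truth(0.2, 0.4)) == 0.0
        assert question_score(ci(0.2, 0.2), truth(0.2, 0.4)) == 1.0  # closed end

    def test_point_truth_scores_by_membership_in_expert_interval(self):
        assert question_score(ci(0.2, 0.6), truth(0.4, 0.4)) == 1.0
        assert question_score(ci(0.2, 0.6), truth(0.7, 0.7)) == 0.0
        assert question_score(ci(0.3, 0.3), truth(0.3, 0.3)) == 1.0

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_score_bounded_and_full_iff_contained(self, a, b, c, d):
        # snap to a 1e-3 grid: containment gaps below float resolution
        # of the overlap subtraction are not meaningful
        lo_e, hi_e = sorted((round(a, 3), round(b, 3)))
        lo_t, hi_t = sorted((round(c, 3), round(d, 3)))
        s = question_score(ci(lo_e, hi_e), truth(lo_t, hi_t))
        assert 0.0 <= s <= 1.0
        if hi_e > lo_e and hi_t > lo_t:
            contained = lo_t <= lo_e and hi_e <= hi_t
            assert (s == 1.0) == contained
        elif hi_e > lo_e:  # point truth scores by membership
            assert (s == 1.0) == (lo_e <= lo_t <= hi_e)

    @given(
        st.floats(0.0, 0.2),
        st.floats(0.1, 0.8),
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance_under_shared_affine_map(self, shift, scale, a, b, c, d):
        """Rescaling both intervals together leaves the score unchanged.

        Endpoints are snapped to a 1e-3 grid so interval widths stay
        well above floating-point cancellation in the mapped overlap.
        """
        shift, scale = round(shift, 3), round(scale, 3) or 0.1
        lo_e, hi_e = sorted((round(a, 3), round(b, 3)))
        lo_t, hi_t = sorted((round(c, 3), round(d, 3)))
        f = lambda x: shift + scale * x  # image stays inside [0, 1]
        base = question_score(ci(lo_e, hi_e), truth(lo_t, hi_t))
        mapped = question_score(ci(f(lo_e), f(hi_e)), truth(f(lo_t), f(hi_t)))
        assert mapped == pytest.approx(base, abs=1e-9)


class TestCalibrateExpert:
    def test_mean_of_scores(self):
        assert calibrate_expert([0.5, 0.3, 0.4, 0.8, 0.0]) == pytest.approx(0.40)
        assert calibrate_expert([1, 1, 1, 1, 1]) == 1.0

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ElicitationError):
            calibrate_expert([])
        with pytest.raises(ElicitationError):
            calibrate_expert([0.5, 1.2])


def panel_records(score_map, truths):
    """Build records whose derived CI realises the given overlap per question.

    Confidence equals the 0.8 target so derivation is the identity;
    the response interval has half the truth's width and slides across
    the truth's upper edge to hit the requested overlap fraction.
    """
    records = []
    for expert, scores in score_map.items():
        for t, p in zip(truths, scores):
            w = t.width / 2
            lo = (t.high + 0.01) if p == 0 else t.high - p * w
            records.append(
                ElicitedInterval(expert, t.question_id, lo, lo + w / 2, lo + w, 0.8)
            )
    return records


class TestCalibratePanel:
    truths = [truth(0.2, 0.4, "Q01"), truth(0.5, 0.7, "Q02")]

    def test_single_expert_matching_truth_weighs_one(self):
        t = [truth(0.2, 0.4, "Q01")]
        records = [ElicitedInterval("E01", "Q01", 0.2, 0.3, 0.4, 0.8)]
        (profile,) = calibrate_panel(records, t)
        assert profile.weight == 1.0

    def test_weights_are_means_of_question_scores(self):
        records = panel_records({"E01": [1.0, 0.0], "E02": [0.5, 0.5]}, self.truths)
        profiles = calibrate_panel(records, self.truths)
        weights = {p.expert_id: p.weight for p in profiles}
        assert weights["E01"] == pytest.approx(0.5)
        assert weights["E02"] == pytest.approx(0.5)
        scores = {p.expert_id: p.question_scores for p in profiles}
        assert scores["E01"]["Q01"] == pytest.approx(1.0)
        assert scores["E01"]["Q02"] == pytest.approx(0.0)

    def test_missing_answer_is_a_hard_error_by_default(self):
        records = panel_records({"E01": [1.0, 0.0]}, self.truths)
        del records[1]
        with pytest.raises(ElicitationError, match="E01.*Q02"):
            calibrate_panel(records, self.truths)
        profiles = calibrate_panel(records, self.truths, missing="ignore")
        assert profiles[0].weight == pytest.approx(1.0)

    def test_weight_invariant_under_question_order(self):
        records = panel_records({"E01": [0.75, 0.25]}, self.truths)
        forward = calibrate_panel(records, self.truths)
        backward = calibrate_panel(list(reversed(records)), list(reversed(self.truths)))
        assert forward[0].weight == backward[0].weight

    def test_profiles_to_frames_shapes(self):
        records = panel_records({"E01": [1.0, 0.0], "E02": [0.5, 0.5]}, self.truths)
        scores, weights = profiles_to_frames(calibrate_panel(records, self.truths))
        assert len(scores) == 4 and len(weights) == 2
        assert set(scores.columns) == {"expert_id", "question_id", "score"}
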