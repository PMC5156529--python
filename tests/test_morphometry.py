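"""Footprint and trackway measurement: definitions, invariances, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ichnos import (Footprint, FootprintMetrics, InsufficientLandmarksError,
                    InvalidArgumentError, Trackway, gait_metrics,
                    measure_footprint, summarize_trackway, trackway_midline)

S1_LENGTHS = [271, 271, 250, 264, 268, 245, 245, 265, 260, 274, 258]
S1_INDICES = [37.2, 36.6, 40.6, 39.7, 41.2, 41.2, 42.4, 40.0, 39.6, 38.6, 42.7]
S1_STEPS = [553, 548, 505, 571, 552, 587, 573, 660]
S1_STRIDES = [1044, 1069, 1140, 1159, 1284]


def _fp(id, side, heel, hallux, ball=None, gap_before=False):
    lm = {"heel_posterior_tip": heel, "hallux_anterior_tip": hallux}
    if ball is not None:
        lm["ball_medial"], lm["ball_lateral"] = ball
    return Footprint(id=id, side=side, landmarks=lm, gap_before=gap_before)


class TestMeasureFootprint:
    @pytest.mark.parametrize("heel,hallux,ball,exp_len,exp_w,exp_idx", [
        # the best-preserved right print: 245 x 104 mm, index 42.4
        ((0, 0), (0, 245), ((-52, 180), (52, 180)), 245.0, 104.0, 42.4),
        ((0, 0), (0, 100), ((-25, 70), (25, 70)), 100.0, 50.0, 50.0),
    ])
    def test_landmark_measures(self, heel, hallux, ball, exp_len, exp_w, exp_idx):
        m = measure_footprint(_fp("t", "right", heel, hallux, ball))
        assert m.length == pytest.approx(exp_len)
        assert m.max_width == pytest.approx(exp_w)
        assert m.foot_index == pytest.approx(exp_idx, abs=0.05)

    @given(angle=st.floats(-math.pi, math.pi),
           tx=st.floats(-1e4, 1e4), ty=st.floats(-1e4, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_rigid_motion_invariance(self, angle, tx, ty):
        R = np.array([[math.cos(angle), -math.sin(angle)],
                      [math.sin(angle), math.cos(angle)]])
        pts = {"heel_posterior_tip": np.array([0.0, 0.0]),
               "hallux_anterior_tip": np.array([0.0, 245.0]),
               "ball_medial": np.array([-52.0, 180.0]),
               "ball_lateral": np.array([52.0, 180.0])}
        moved = {k: R @ v + np.array([tx, ty]) for k, v in pts.items()}
        m0 = measure_footprint(Footprint(id="a", side="right", landmarks=pts))
        m1 = measure_footprint(Footprint(id="b", side="right", landmarks=moved))
        assert m1.length == pytest.approx(m0.length, rel=1e-9)
        assert m1.max_width == pytest.approx(m0.max_width, rel=1e-9)

    def test_missing_landmark_named_in_error(self):
        fp = Footprint(id="x", side="left",
                       landmarks={"heel_posterior_tip": (0, 0)})
        with pytest.raises(InsufficientLandmarksError, match="hallux_anterior_tip"):
            measure_footprint(fp)

    def test_zero_axis_rejected(self):
        fp = _fp("x", "left", (0, 0), (0, 245), ((-52, 180), (52, 180)))
        with pytest.raises(InvalidArgumentError):
            measure_footprint(fp, axis=(0.0, 0.0))

    def test_outline_caliper_fallback(self):
        from ichnos import footprint_template
        outline, lm = footprint_template(261.0, 104.0, 81.0)
        fp = Footprint(id="o", side="right", outline=outline,
                       landmarks={"heel_posterior_tip": lm["heel_posterior_tip"],
                                  "hallux_anterior_tip": lm["hallux_anterior_tip"]})
        m = measure_footprint(fp)
        assert m.length == pytest.approx(261.0)
        assert m.max_width == pytest.approx(104.0, abs=1.0)
        assert m.heel_width == pytest.approx(81.0, abs=1.5)


class TestMidline:
    def test_symmetric_stagger_gives_axis_parallel_midline(self):
        fps = [_fp(f"p{i}", s, h, (h[0], h[1] + 250))
               for i, (s, h) in enumerate([("right", (0, 0)), ("left", (60, 550)),
                                           ("right", (0, 1100)), ("left", (60, 1650))])]
        point, d = trackway_midline(Trackway(individual_id="t", footprints=fps))
        assert abs(d[0]) < 1e-12 and d[1] == pytest.approx(1.0)
        assert point[0] == pytest.approx(30.0)

    def test_collinear_diagonal(self):
        fps = [_fp(f"p{i}", ["right", "left"][i % 2], (v, v), (v, v + 250))
               for i, v in enumerate([0, 400, 800])]
        _, d = trackway_midline(Trackway(individual_id="t", footprints=fps))
        assert d == pytest.approx([math.sqrt(2) / 2] * 2)

    def test_underdetermined(self):
        tw = Trackway(individual_id="t", footprints=[_fp("p", "left", (0, 0), (0, 250))])
        with pytest.raises(InvalidArgumentError, match="underdetermined"):
            trackway_midline(tw)


class TestGaitMetrics:
    def test_single_step_axis_aligned(self):
        fps = [_fp("a", "right", (0, 0), (0, 250)),
               _fp("b", "left", (0, 568), (0, 818))]
        g = gait_metrics(Trackway(individual_id="t", footprints=fps))
        assert g.step_lengths == [("a", "b", pytest.approx(568.0))]

    def test_step_is_euclidean(self):
        fps = [_fp("a", "right", (0, 0), (0, 250)),
               _fp("b", "left", (120, 540), (120, 790))]
        g = gait_metrics(Trackway(individual_id="t", footprints=fps))
        assert g.step_lengths[0][2] == pytest.approx(math.hypot(120, 540), abs=0.05)

    def test_stride_spans_one_opposite_print(self):
        fps = [_fp("a", "right", (0, 0), (0, 250)),
               _fp("b", "left", (80, 550), (80, 800)),
               _fp("c", "right", (0, 1139), (0, 1389))]
        g = gait_metrics(Trackway(individual_id="t", footprints=fps))
        assert g.stride_lengths == [("a", "c", pytest.approx(1139.0))]

    def test_gap_skips_pairs(self):
        fps = [_fp("a", "right", (0, 0), (0, 250)),
               _fp("b", "left", (80, 550), (80, 800), gap_before=True),
               _fp("c", "right", (0, 1139), (0, 1389))]
        g = gait_metrics(Trackway(individual_id="t", footprints=fps))
        assert g.step_lengths == [("b", "c", pytest.approx(math.hypot(80, 589)))]
        assert g.stride_lengths == []
        assert any("gap" in reason for *_, reason in g.skipped_pairs)

    def test_triangle_inequality_stride_vs_steps(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            heels = rng.uniform(0, 1000, size=(3, 2))
            fps = [_fp(f"p{i}", ["right", "left", "right"][i], h, h + [0, 250])
                   for i, h in enumerate(heels)]
            g = gait_metrics(Trackway(individual_id="t", footprints=fps))
            stride = g.stride_lengths[0][2]
            assert stride <= sum(v for *_, v in g.step_lengths) + 1e-9


class TestSummaries:
    def test_s1_mean_length_261(self):
        metrics = [FootprintMetrics(length=L, max_width=100) for L in S1_LENGTHS]
        s = summarize_trackway("S1", metrics)
        assert s.length_mean == pytest.approx(261.0)
        assert s.length_range == (245, 274)

    def test_s1_mean_foot_index_40(self, fixtures):
        fp = fixtures["table2_footprints"]
        idx = fp[fp["individual_id"] == "S1"]["foot_index_pct"].dropna()
        assert len(idx) == 11
        assert float(idx.mean()) == pytest.approx(40.0, abs=0.05)

    def test_printed_indices_match_recomputed_within_rounding(self, fixtures):
        fp = fixtures["table2_footprints"]
        rows = fp[(fp["individual_id"] == "S1") & fp["length_mm"].notna()]
        recomputed = 100.0 * rows["max_width_mm"] / rows["length_mm"]
        assert (recomputed - rows["foot_index_pct"]).abs().max() <= 0.3

    def test_printed_step_and_stride_means(self):
        assert 568 <= np.mean(S1_STEPS) <= 569
        assert 1139 <= np.mean(S1_STRIDES) <= 1140

    def test_single_footprint_sd_undefined(self):
        s = summarize_trackway("X", [FootprintMetrics(length=250, max_width=100)])
        assert s.length_mean == 250 and s.length_sd is None
        assert s.length_range == (250, 250)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError, match="no measurable footprints"):
            summarize_trackway("X", [])
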