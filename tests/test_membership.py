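"""Membership-function construction, fuzzification, and calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fuzzymotion import (
    CalibrationConstants,
    CalibrationError,
    LabeledRecording,
    build_grid,
    calibrate,
    fuzzify,
    fuzzify_many,
)
from fuzzymotion.vocab import FUZZY_LABELS, REST, ULNAR_DEVIATION, WRIST_EXTENSION

from oracles import segment_means_by_label


class TestBuildGrid:
    @pytest.mark.parametrize(
        "anchors, peaks",
        [
            # direct substitution into the breakpoint formulas
            ((-1.0, 0.0, 1.0), (-1.5, -1.0, 0.0, 0.5, 1.0, 1.5)),
            ((-2.0, 0.0, 2.0), (-3.0, -2.0, 0.0, 1.0, 2.0, 3.0)),
            # asymmetric anchors, hand-evaluated before implementation
            ((-0.4, 0.1, 0.9), (-0.65, -0.4, 0.1, 0.5, 0.9, 1.4)),
        ],
    )
    def test_peak_positions(self, anchors, peaks):
        grid = build_grid(CalibrationConstants(*anchors))
        assert grid.peaks == pytest.approx(peaks)
        assert grid.outer_neg == pytest.approx(peaks[0])
        assert grid.outer_pos == pytest.approx(peaks[5])

    @pytest.mark.parametrize("anchors", [(0.0, 0.0, 1.0), (0.5, 0.0, 1.0), (-1.0, 1.0, 1.0), (-1.0, 2.0, 1.0)])
    def test_rejects_unordered_anchors(self, anchors):
        with pytest.raises(CalibrationError, match="x_n < x_o < x_p"):
            CalibrationConstants(*anchors)


class TestFuzzify:
    def test_peak_identity(self, grid):
        """At each triangle peak exactly that label has weight one."""
        for i, peak in enumerate(grid.peaks):
            w = fuzzify(peak, grid)
            expected = np.zeros(6)
            expected[i] = 1.0
            np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_saturation_beyond_boundaries(self, grid):
        for v in (grid.outer_pos + 0.1, grid.outer_pos + 5.0):
            np.testing.assert_array_equal(fuzzify(v, grid), [0, 0, 0, 0, 0, 1])
        for v in (grid.outer_neg, grid.outer_neg - 0.1, grid.outer_neg - 5.0):
            np.testing.assert_array_equal(fuzzify(v, grid), [1, 0, 0, 0, 0, 0])

    def test_midpoint_splits_weight_evenly(self, grid):
        """Halfway between adjacent peaks the two labels share weight 0.5/0.5."""
        w = fuzzify(0.25, grid)  # midpoint of Off (0.0) and Low (0.5) peaks
        assert dict(zip(FUZZY_LABELS, w)) == pytest.approx(
            {"High_N": 0, "Low_N": 0, "Off": 0.5, "Low": 0.5, "Med": 0, "High": 0}
        )

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_rejects_non_finite(self, bad, grid):
        with pytest.raises(CalibrationError):
            fuzzify(bad, grid)

    @given(v=st.floats(min_value=-4.0, max_value=4.0, allow_nan=False))
    def test_partition_of_unity_and_sparsity(self, v):
        grid = build_grid(CalibrationConstants(-1.0, 0.0, 1.0))
        w = fuzzify(v, grid)
        assert np.all(w >= 0) and np.all(w <= 1)
        assert np.count_nonzero(w) <= 2
        if grid.outer_neg < v < grid.outer_pos:
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
        else:
            assert np.count_nonzero(w == 1.0) == 1 and w.sum() == 1.0

    def test_continuity_at_breakpoints(self, grid):
        """Weights are continuous across every branch boundary."""
        eps = 1e-9
        for p in grid.peaks:
            lo, at, hi = (fuzzify(p + d, grid) for d in (-eps, 0.0, eps))
            np.testing.assert_allclose(lo, at, atol=1e-8)
            np.testing.assert_allclose(hi, at, atol=1e-8)

    def test_vectorized_matches_scalar(self, grid):
        rng = np.random.default_rng(42)
        v = rng.uniform(-3, 3, size=200)
        batch = fuzzify_many(v, grid)
        for vi, row in zip(v, batch):
            np.testing.assert_array_equal(row, fuzzify(vi, grid))


class TestCalibrate:
    def test_means_of_listed_values(self):
        """WE negatives {-1,-3}, rest {0,0}, positives {2,2} -> (-2, 0, 2)."""
        rec = LabeledRecording(
            sample_rate=10.0,
            channel_1=[-1.0, 0.0, 2.0],
            channel_2=[-3.0, 0.0, 2.0],
            labels=[WRIST_EXTENSION, REST, ULNAR_DEVIATION],
        )
        c = calibrate(rec)
        assert (c.x_n, c.x_o, c.x_p) == (-2.0, 0.0, 2.0)

    def test_missing_rest_segment_rejected(self):
        rec = LabeledRecording(
            sample_rate=10.0,
            channel_1=[-1.0, 2.0],
            channel_2=[-1.0, 2.0],
            labels=[WRIST_EXTENSION, ULNAR_DEVIATION],
        )
        with pytest.raises(CalibrationError, match="rest"):
            calibrate(rec)

    def test_diagnostic_names_violated_ordering(self):
        rec = LabeledRecording(
            sample_rate=10.0,
            channel_1=[-0.1, -5.0, 2.0],
            channel_2=[-0.1, -5.0, 2.0],
            labels=[WRIST_EXTENSION, REST, ULNAR_DEVIATION],
        )
        with pytest.raises(CalibrationError, match="x_n < x_o < x_p"):
            calibrate(rec)

    def test_recovers_known_plateau_means(self):
        """On a 100-sample noisy recording, anchors equal an independent
        one-pass recomputation of the segment means."""
        rng = np.random.default_rng(7)
        labels = [REST] * 40 + [WRIST_EXTENSION] * 30 + [ULNAR_DEVIATION] * 30
        level = {REST: 0.0, WRIST_EXTENSION: -1.0, ULNAR_DEVIATION: 1.0}
        clean = np.array([level[l] for l in labels])
        rec = LabeledRecording(
            sample_rate=100.0,
            channel_1=clean + 0.05 * rng.standard_normal(100),
            channel_2=clean + 0.05 * rng.standard_normal(100),
            labels=labels,
        )
        c = calibrate(rec)
        assert c.x_n == pytest.approx(segment_means_by_label(rec, WRIST_EXTENSION, "neg"))
        assert c.x_o == pytest.approx(segment_means_by_label(rec, REST))
        assert c.x_p == pytest.approx(segment_means_by_label(rec, ULNAR_DEVIATION, "pos"))
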