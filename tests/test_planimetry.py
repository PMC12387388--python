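import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from planim.errors import ValidationError
from planim.planimetry import (
    binarize,
    find_orifice_contour,
    max_opening_frame,
    threshold_scan,
    to_grayscale,
)
from planim.video_io import explicit_calibration

from conftest import gray_frame


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((0, 0, 0), 0),
            ((255, 255, 255), 255),  # 254.9745 rounds up
            ((100, 100, 100), 100),  # 99.99 rounds up
            ((10, 200, 30), 124),  # 2.989 + 117.4 + 3.42 = 123.809
            ((255, 0, 0), 76),  # 76.2195 rounds down
        ],
    )
    def test_luminance_examples(self, rgb, expected):
        frame = np.array([[rgb]], dtype=np.uint8)
        assert to_grayscale(frame)[0, 0] == expected

    def test_preserves_shape(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, (7, 9, 3), dtype=np.uint8)
        assert to_grayscale(frame).shape == (7, 9)


class TestBinarize:
    def test_strictly_above_threshold_is_one(self):
        gray = np.array([[21, 20, 19]], dtype=np.uint8)
        assert binarize(gray, 20).tolist() == [[1, 0, 0]]

    @pytest.mark.parametrize("t", [0, 255, -3, 300])
    def test_threshold_outside_open_interval_rejected(self, t):
        with pytest.raises(ValidationError):
            binarize(np.zeros((2, 2), dtype=np.uint8), t)

    @settings(max_examples=30, deadline=None)
    @given(arrays(np.uint8, (16, 16), elements=st.integers(0, 60)))
    def test_monotone_shrinkage_of_bright_set(self, gray):
        """Raising the threshold can only turn bright pixels dark."""
        for t in range(10, 30):
            lo, hi = binarize(gray, t), binarize(gray, t + 1)
            assert not np.any(hi > lo)


class TestOrificeContour:
    def test_square_hole_area_and_perimeter(self, square_hole_mask, cal_01):
        c = find_orifice_contour(square_hole_mask, cal_01)
        assert c.interior_pixel_count == 100
        assert c.area_cm2 == pytest.approx(1.0)
        # boundary through pixel centers: 4 sides of 9 steps at 0.1 cm
        assert c.perimeter_cm == pytest.approx(3.6)
        assert len(c.boundary) == 36

    def test_no_hole_returns_none(self, cal_01):
        assert find_orifice_contour(np.ones((5, 5), dtype=np.uint8), cal_01) is None

    def test_border_touching_dark_region_is_background(self, cal_01):
        mask = np.ones((6, 6), dtype=np.uint8)
        mask[0:3, 2] = 0
        assert find_orifice_contour(mask, cal_01) is None

    def test_largest_enclosed_region_wins(self, cal_01):
        mask = np.ones((20, 30), dtype=np.uint8)
        mask[5:8, 5:8] = 0  # 9 px
        mask[5:15, 15:25] = 0  # 100 px
        c = find_orifice_contour(mask, cal_01)
        assert c.interior_pixel_count == 100

    def test_single_pixel_hole(self, cal_01):
        mask = np.ones((5, 5), dtype=np.uint8)
        mask[2, 2] = 0
        c = find_orifice_contour(mask, cal_01)
        assert c.interior_pixel_count == 1
        assert c.perimeter_cm == 0.0

    @pytest.mark.parametrize("k", [2.0, 0.5, 3.7])
    def test_area_scales_k2_perimeter_scales_k(self, square_hole_mask, cal_01, k):
        base = find_orifice_contour(square_hole_mask, cal_01)
        scaled = find_orifice_contour(square_hole_mask, cal_01.scaled(k))
        assert scaled.area_cm2 == pytest.approx(base.area_cm2 * k * k)
        assert scaled.perimeter_cm == pytest.approx(base.perimeter_cm * k)

    def test_anisotropic_pixels(self, square_hole_mask):
        cal = explicit_calibration(0.2, 0.1)
        c = find_orifice_contour(square_hole_mask, cal)
        assert c.area_cm2 == pytest.approx(100 * 0.02)
        # two horizontal sides at 0.2 cm/step, two vertical at 0.1
        assert c.perimeter_cm == pytest.approx(2 * 9 * 0.2 + 2 * 9 * 0.1)

    def test_boundary_is_closed_8_connected_path(self, cal_01):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mask = (rng.random((15, 15)) > 0.4).astype(np.uint8)
            mask[[0, -1], :] = 1
            mask[:, [0, -1]] = 1
            c = find_orifice_contour(mask, cal_01)
            if c is None:
                continue
            steps = np.abs(
                np.diff(np.vstack([c.boundary, c.boundary[:1]]), axis=0)
            ).max(axis=1)
            assert steps.max() <= 1


class TestMaxOpeningFrame:
    def test_finds_true_peak_frame(self, mild_phantom, cal_01):
        spec, frames, truth = mild_phantom
        rec = max_opening_frame(list(frames), 25, truth.calibration)
        assert rec.best_frame_index == truth.peak_frame

    def test_all_closed_scores_zero(self, cal_01):
        frames = [gray_frame(np.full((10, 10), 200))] * 3
        rec = max_opening_frame(frames, 20, cal_01)
        assert rec.area_cm2 == 0.0
        assert rec.perimeter_cm == 0.0

    def test_tie_goes_to_earliest_frame(self, cal_01):
        v = np.full((12, 12), 200)
        v[4:8, 4:8] = 0
        frames = [gray_frame(v), gray_frame(v)]
        rec = max_opening_frame(frames, 20, cal_01)
        assert rec.best_frame_index == 0


def _jump_frame():
    """One frame whose orifice expands drastically at threshold 17.

    A 10×10 hole of gray 5 sits next to a 10×8 region of gray 17 inside
    gray-200 tissue.  For thresholds up to 16 the gray-17 region counts
    as bright; from 17 on it joins the hole and the contour perimeter
    jumps from 3.6 cm to 5.2 cm.
    """
    v = np.full((40, 40), 200)
    v[15:25, 15:25] = 5
    v[15:25, 25:33] = 17
    return gray_frame(v)


class TestThresholdScan:
    def test_perimeter_jump_selects_penultimate_threshold(self, cal_01):
        res = threshold_scan([_jump_frame()], cal_01)
        assert res.stop_reason == "perimeter_jump"
        assert res.selected_threshold == 16
        assert res.records[-1].threshold == 17
        assert res.mva_cm2 == pytest.approx(1.0)

    def test_stable_contour_runs_to_cap(self, mild_phantom):
        spec, frames, truth = mild_phantom
        res = threshold_scan(list(frames), truth.calibration)
        assert res.stop_reason == "threshold_cap"
        assert res.selected_threshold == 30
        assert res.mva_cm2 == pytest.approx(truth.max_area_cm2, rel=0.02)

    def test_mva_equals_selected_record_area(self, mild_phantom):
        spec, frames, truth = mild_phantom
        res = threshold_scan(list(frames), truth.calibration)
        assert res.mva_cm2 == res.selected_record.area_cm2
        assert res.selected_frame_index == res.selected_record.best_frame_index

    def test_empty_sequence_rejected(self, cal_01):
        with pytest.raises(ValidationError):
            threshold_scan([], cal_01)

    def test_inverted_bounds_rejected(self, cal_01):
        with pytest.raises(ValidationError):
            threshold_scan([gray_frame(np.zeros((4, 4)))], cal_01, t_min=20, t_max=10)

    def test_matches_bruteforce_oracle(self, mild_phantom):
        """Scan result equals an independent full enumeration with the
        stop rule applied afterwards."""
        spec, frames, truth = mild_phantom
        res = threshold_scan(list(frames), truth.calibration)
        oracle = bruteforce_scan(list(frames), truth.calibration)
        assert res.selected_threshold == oracle["selected_threshold"]
        assert res.selected_frame_index == oracle["selected_frame_index"]
        assert res.mva_cm2 == pytest.approx(oracle["mva_cm2"])
        assert res.stop_reason == oracle["stop_reason"]


def bruteforce_scan(frames, calibration, t_min=10, t_max=30, jump=1.0):
    """Independent oracle: evaluate every threshold, then apply the stop
    rule post hoc over the precomputed records."""
    recs = [max_opening_frame(frames, t, calibration) for t in range(t_min, t_max + 1)]
    selected, reason = recs[-1], "threshold_cap"
    for prev, cur in zip(recs, recs[1:]):
        if abs(cur.perimeter_cm - prev.perimeter_cm) > jump:
            selected, reason = prev, "perimeter_jump"
            break
    return {
        "selected_threshold": selected.threshold,
        "selected_frame_index": selected.best_frame_index,
        "mva_cm2": selected.area_cm2,
        "stop_reason": reason,
    }
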