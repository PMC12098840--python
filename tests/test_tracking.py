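"""ROI-threshold detection, chamber classification, locomotion metrics."""

import math

import numpy as np
import pytest

from magstim.errors import TrackingError
from magstim.tracking import (
    ROI,
    ChamberTimeline,
    DetectionConfig,
    Trajectory,
    binarize,
    centroid,
    chamber_times,
    classify_light_dark,
    classify_three_chamber,
    count_target_pixels,
    locomotion_metrics,
)

from oracles import median_threshold_bruteforce

CFG3 = DetectionConfig(blur_kernel=3)


class TestBinarize:
    def test_blank_white_frame_has_no_black_pixels(self):
        frame = np.full((20, 20), 255, dtype=np.uint8)
        mask = binarize(frame, ROI(0, 0, 20, 20), CFG3)
        assert count_target_pixels(mask, "black") == 0

    def test_all_dark_frame_is_fully_black(self):
        frame = np.zeros((20, 20), dtype=np.uint8)
        mask = binarize(frame, ROI(0, 0, 20, 20), CFG3)
        assert count_target_pixels(mask, "black") == 400

    def test_matches_pixelwise_bruteforce_oracle(self):
        """5x5 dark block on white, kernel 3, against brute-force median."""
        frame = np.full((9, 9), 255, dtype=np.uint8)
        frame[2:7, 2:7] = 0
        mask = binarize(frame, ROI(0, 0, 9, 9), CFG3)
        expected = median_threshold_bruteforce(frame, 3, 127)
        np.testing.assert_array_equal(mask, expected)

    def test_oracle_agreement_on_noisy_frames(self):
        rng = np.random.default_rng(13)
        for kernel in (3, 5):
            frame = rng.integers(0, 256, size=(15, 12), dtype=np.uint8)
            cfg = DetectionConfig(blur_kernel=kernel)
            mask = binarize(frame, ROI(0, 0, 12, 15), cfg)
            expected = median_threshold_bruteforce(frame, kernel, 127)
            np.testing.assert_array_equal(mask, expected)

    def test_idempotent_on_binary_with_kernel_1(self):
        rng = np.random.default_rng(3)
        binary = rng.choice([0, 255], size=(10, 10)).astype(np.uint8)
        cfg = DetectionConfig(blur_kernel=1)
        once = binarize(binary, ROI(0, 0, 10, 10), cfg)
        twice = binarize(once, ROI(0, 0, 10, 10), cfg)
        np.testing.assert_array_equal(once, binary)
        np.testing.assert_array_equal(twice, once)

    def test_kernel_larger_than_roi_rejected(self):
        frame = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(TrackingError, match="kernel"):
            binarize(frame, ROI(0, 0, 3, 3), DetectionConfig(blur_kernel=5))

    def test_roi_must_fit_frame(self):
        frame = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(TrackingError):
            binarize(frame, ROI(5, 5, 10, 10), CFG3)


class TestCounting:
    def test_empty_and_full(self):
        assert count_target_pixels(np.full((5, 5), 255, np.uint8), "black") == 0
        assert count_target_pixels(np.zeros((5, 5), np.uint8), "black") == 25

    def test_checkerboard(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255
        assert count_target_pixels(board.astype(np.uint8), "black") == 8
        assert count_target_pixels(board.astype(np.uint8), "white") == 8

    def test_count_plus_inverse_is_area(self):
        rng = np.random.default_rng(8)
        mask = rng.choice([0, 255], size=(13, 7)).astype(np.uint8)
        total = count_target_pixels(mask, "black") + count_target_pixels(mask, "white")
        assert total == 13 * 7

    def test_non_binary_rejected(self):
        with pytest.raises(TrackingError):
            count_target_pixels(np.array([[0, 128]], dtype=np.uint8), "black")


class TestChamberRules:
    def test_light_dark_rule(self):
        assert classify_light_dark(0, 50) == "dark"
        assert classify_light_dark(500, 50) == "light"

    def test_light_dark_tie_counts_as_in_roi(self):
        assert classify_light_dark(50, 50) == "light"

    def test_three_chamber_roi_hit_means_middle_with_memory(self):
        chamber, state = classify_three_chamber(120, 0, (50, 50), "unknown")
        assert chamber == "middle" and state == "middle-near-left"
        chamber, state = classify_three_chamber(0, 80, (50, 50), state)
        assert chamber == "middle" and state == "middle-near-right"

    def test_three_chamber_side_from_memory(self):
        chamber, state = classify_three_chamber(0, 0, (50, 50), "middle-near-right")
        assert chamber == "right" and state == "right"
        chamber, _ = classify_three_chamber(0, 0, (50, 50), "left")
        assert chamber == "left"

    def test_three_chamber_first_frame_undetermined(self):
        chamber, state = classify_three_chamber(0, 0, (50, 50), "unknown")
        assert chamber == "undetermined" and state == "unknown"


class TestCentroid:
    def test_single_pixel(self):
        mask = np.full((6, 6), 255, np.uint8)
        mask[4, 3] = 0  # row y=4, col x=3
        assert centroid(mask, "black") == (3.0, 4.0)

    def test_filled_block_at_origin(self):
        mask = np.full((6, 6), 255, np.uint8)
        mask[0:4, 0:4] = 0
        assert centroid(mask, "black") == (1.5, 1.5)

    def test_symmetric_blob_centered(self):
        mask = np.full((21, 21), 255, np.uint8)
        ys, xs = np.mgrid[0:21, 0:21]
        mask[(xs - 10) ** 2 + (ys - 10) ** 2 <= 36] = 0
        assert centroid(mask, "black") == (10.0, 10.0)

    def test_no_target_pixels_gives_none(self):
        assert centroid(np.full((5, 5), 255, np.uint8), "black") is None


class TestLocomotion:
    def test_stationary_blob(self):
        traj = Trajectory(points=[(5.0, 5.0)] * 10, scale_mm_per_px=1.0, fps=30.0)
        summary = locomotion_metrics(traj)
        assert summary.total_distance_m == 0.0
        assert summary.mean_speed_mm_s == 0.0

    def test_straight_line_hand_arithmetic(self):
        """300 frames at 10 px/frame, 1 mm/px, 30 fps: 2.99 m, 300 mm/s."""
        pts = [(10.0 * i, 0.0) for i in range(300)]
        summary = locomotion_metrics(Trajectory(points=pts, scale_mm_per_px=1.0, fps=30.0))
        assert summary.total_distance_m == pytest.approx(2.99, abs=1e-12)
        assert summary.mean_speed_mm_s == pytest.approx(300.0, abs=1e-9)

    def test_absent_frames_are_bridged(self):
        pts = [(0.0, 0.0), None, (2.0, 0.0), (3.0, 0.0)]
        summary = locomotion_metrics(Trajectory(points=pts, scale_mm_per_px=1.0, fps=1.0))
        assert summary.total_distance_m == pytest.approx(3e-3, abs=1e-15)
        assert summary.n_steps == 2

    def test_circular_path_approaches_circumference(self):
        n, radius = 720, 100.0
        pts = [
            (radius * math.cos(2 * math.pi * i / n), radius * math.sin(2 * math.pi * i / n))
            for i in range(n + 1)
        ]
        summary = locomotion_metrics(Trajectory(points=pts, scale_mm_per_px=1.0, fps=30.0))
        circumference_m = 2 * math.pi * radius / 1000.0
        assert summary.total_distance_m == pytest.approx(circumference_m, rel=1e-4)
        assert summary.total_distance_m <= circumference_m  # inscribed polygon

    def test_too_few_centroids_rejected(self):
        with pytest.raises(TrackingError):
            locomotion_metrics(
                Trajectory(points=[(0.0, 0.0), None], scale_mm_per_px=1.0, fps=30.0)
            )


class TestChamberTimes:
    def test_all_dark(self):
        result = chamber_times(ChamberTimeline(labels=["dark"] * 40, fps=20.0))
        assert result["dark_fraction"] == 1.0
        assert result["seconds"]["dark"] == pytest.approx(2.0)

    def test_fractions_from_counts(self):
        labels = ["dark"] * 30 + ["light"] * 70
        result = chamber_times(ChamberTimeline(labels=labels, fps=12.5))
        assert result["dark_fraction"] == pytest.approx(0.30, abs=1e-12)
        assert sum(result["fractions"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_undetermined_excluded_from_denominator(self):
        labels = ["dark"] * 30 + ["light"] * 30 + ["undetermined"] * 40
        result = chamber_times(ChamberTimeline(labels=labels, fps=10.0))
        assert result["dark_fraction"] == pytest.approx(0.5, abs=1e-12)
        assert result["seconds"]["undetermined"] == pytest.approx(4.0)
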