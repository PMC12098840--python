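"""ROI-threshold rodent tracking on grayscale frames.

Two chamber-detection algorithms plus centroid locomotion metrics, matching
the closed-loop video pipeline of the platform this toolkit models:

* **light-dark box**: the camera images only the light box.  The ROI is
  cropped, median-blurred, and thresholded at an intensity cutoff
  (127 by default); a dark (black) subject against a white background is
  detected by the count of black pixels.  Count >= pixel threshold means
  the subject is visible, i.e. in the light chamber; below means it is in
  the (unimaged) dark chamber.
* **three-chamber**: the camera images the middle chamber with an ROI at
  each side.  If either ROI's black count reaches its threshold the subject
  is in the middle chamber and the nearer side is remembered; when both
  counts fall below threshold the subject has entered the side chamber it
  was last seen nearest.

Pixel coordinates: x = column, y = row, origin top-left; centroids are
float pixels.  Color frames should be reduced to grayscale with the
standard luma weights (0.299, 0.587, 0.114) before processing
(:func:`to_grayscale`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import median_filter

from .errors import TrackingError

__all__ = [
    "ROI",
    "DetectionConfig",
    "Trajectory",
    "ChamberTimeline",
    "to_grayscale",
    "binarize",
    "count_target_pixels",
    "classify_light_dark",
    "classify_three_chamber",
    "centroid",
    "locomotion_metrics",
    "chamber_times",
    "LocomotionSummary",
]

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ROI:
    """Pixel rectangle [x, x+width) x [y, y+height) inside a frame."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise TrackingError("ROI extents must be positive")
        if self.x < 0 or self.y < 0:
            raise TrackingError("ROI origin must be non-negative")

    def validate_in(self, frame: np.ndarray) -> None:
        h, w = frame.shape[:2]
        if self.x + self.width > w or self.y + self.height > h:
            raise TrackingError(
                f"ROI {self} extends beyond the {w}x{h} frame"
            )

    def crop(self, frame: np.ndarray) -> np.ndarray:
        self.validate_in(frame)
        return frame[self.y : self.y + self.height, self.x : self.x + self.width]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholding parameters of the subject detector."""

    intensity_threshold: int = 127
    blur_kernel: int = 5
    pixel_count_threshold: int = 50
    target_color: str = "black"

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_threshold <= 255:
            raise TrackingError("intensity_threshold must be in 0..255")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise TrackingError("blur_kernel must be an odd integer >= 1")
        if self.target_color not in ("black", "white"):
            raise TrackingError("target_color must be 'black' or 'white'")


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Reduce an RGB frame to 8-bit grayscale with luma weights."""
    if frame.ndim == 2:
        return frame.astype(np.uint8, copy=False)
    weights = np.array([0.299, 0.587, 0.114])
    return np.clip(frame[..., :3] @ weights, 0, 255).astype(np.uint8)


def _check_gray(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise TrackingError("expected a 2D grayscale frame")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise TrackingError("grayscale values must lie in 0..255")
        arr = arr.astype(np.uint8)
    return arr


def binarize(frame: np.ndarray, roi: ROI, config: DetectionConfig) -> np.ndarray:
    """Crop, median-blur, and threshold an ROI into a 0/255 mask.

    Intensity > threshold maps to white (255), <= threshold to black (0);
    the blur uses replicated borders.  Idempotent on already-binary input
    with kernel 1.
    """
    crop = roi.crop(_check_gray(frame))
    if config.blur_kernel > min(crop.shape):
        raise TrackingError(
            f"blur kernel {config.blur_kernel} exceeds the ROI extent {crop.shape}"
        )
    if config.blur_kernel > 1:
        crop = median_filter(crop, size=config.blur_kernel, mode="nearest")
    return np.where(crop > config.intensity_threshold, 255, 0).astype(np.uint8)


def count_target_pixels(mask: np.ndarray, target_color: str = "black") -> int:
    """Exact count of mask pixels matching the target color."""
    arr = np.asarray(mask)
    if arr.size and not np.isin(arr, (0, 255)).all():
        raise TrackingError("mask is not binary (values must be 0 or 255)")
    if target_color == "black":
        return int(np.count_nonzero(arr == 0))
    if target_color == "white":
        return int(np.count_nonzero(arr == 255))
    raise TrackingError("target_color must be 'black' or 'white'")


def classify_light_dark(target_count: int, pixel_count_threshold: int) -> str:
    """Light-dark chamber rule: subject visible in the imaged light box?

    count >= threshold -> "light" (ties count as in-ROI); below -> "dark".
    """
    if target_count < 0 or pixel_count_threshold < 0:
        raise TrackingError("counts must be >= 0")
    return "light" if target_count >= pixel_count_threshold else "dark"


#: side-memory states of the three-chamber tracker
_NEAR = {"left": "middle-near-left", "right": "middle-near-right"}
_SIDE_OF = {
    "middle-near-left": "left",
    "middle-near-right": "right",
    "left": "left",
    "right": "right",
}


def classify_three_chamber(
    count_left_roi: int,
    count_right_roi: int,
    thresholds: Tuple[int, int],
    previous_state: str = "unknown",
) -> Tuple[str, str]:
    """Three-chamber rule; returns (chamber, new_state).

    The camera images the middle chamber with a left and a right ROI.
    If either ROI count reaches its threshold the subject is in the middle
    chamber (memory updated to the triggered side; with both triggered, the
    larger count wins).  If both are below, the subject is in the side
    chamber matching the remembered side; with no memory the result is
    ``"undetermined"``.
    """
    thr_left, thr_right = thresholds
    in_left = count_left_roi >= thr_left
    in_right = count_right_roi >= thr_right
    if in_left or in_right:
        if in_left and in_right:
            side = "left" if count_left_roi >= count_right_roi else "right"
        else:
            side = "left" if in_left else "right"
        return "middle", _NEAR[side]
    if previous_state in _SIDE_OF:
        side = _SIDE_OF[previous_state]
        return side, side
    return UNDETERMINED, "unknown"


def centroid(mask: np.ndarray, target_color: str = "black") -> Optional[Tuple[float, float]]:
    """Arithmetic mean (x, y) of target pixels, or None if there are none."""
    arr = np.asarray(mask)
    match = arr == (0 if target_color == "black" else 255)
    ys, xs = np.nonzero(match)
    if xs.size == 0:
        return None
    return float(xs.mean()), float(ys.mean())


@dataclass
class Trajectory:
    """Per-frame centroids in pixels (None where the subject was absent)."""

    points: List[Optional[Tuple[float, float]]]
    scale_mm_per_px: float
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise TrackingError("fps must be > 0")
        if self.scale_mm_per_px <= 0:
            raise TrackingError("scale_mm_per_px must be > 0")


@dataclass(frozen=True)
class LocomotionSummary:
    total_distance_m: float
    mean_speed_mm_s: float
    n_steps: int


def locomotion_metrics(trajectory: Trajectory) -> LocomotionSummary:
    """Total path length and mean speed from frame-to-frame displacements.

    Frames with an absent centroid are bridged: the displacement is taken
    to the next frame with a detection.  Mean speed is total distance over
    the full elapsed time ``(n_frames - 1) / fps``.
    """
    present = [(i, p) for i, p in enumerate(trajectory.points) if p is not None]
    if len(present) < 2:
        raise TrackingError("locomotion metrics need at least 2 detected centroids")
    dist_px = 0.0
    steps = 0
    for (_, a), (_, b) in zip(present, present[1:]):
        dist_px += float(np.hypot(b[0] - a[0], b[1] - a[1]))
        steps += 1
    dist_mm = dist_px * trajectory.scale_mm_per_px
    elapsed = (len(trajectory.points) - 1) / trajectory.fps
    return LocomotionSummary(
        total_distance_m=dist_mm / 1000.0,
        mean_speed_mm_s=dist_mm / elapsed,
        n_steps=steps,
    )


@dataclass
class ChamberTimeline:
    """Per-frame chamber labels at a fixed frame rate."""

    labels: List[str]
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise TrackingError("fps must be > 0")


def chamber_times(timeline: ChamberTimeline) -> dict:
    """Cumulative seconds per chamber plus occupancy fractions.

    Each frame contributes 1/fps to its label.  Undetermined frames
    accumulate their own time but are excluded from the fraction
    denominator.  Returns ``{"seconds": {...}, "fractions": {...},
    "dark_fraction": float | None}``.
    """
    seconds: dict = {}
    for label in timeline.labels:
        seconds[label] = seconds.get(label, 0.0) + 1.0 / timeline.fps
    determined = {k: v for k, v in seconds.items() if k != UNDETERMINED}
    total = sum(determined.values())
    fractions = {k: v / total for k, v in determined.items()} if total else {}
    dark_fraction = fractions.get("dark") if "dark" in fractions else None
    return {"seconds": seconds, "fractions": fractions, "dark_fraction": dark_fraction}
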