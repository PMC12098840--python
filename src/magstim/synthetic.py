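"""Synthetic experiments: virtual arenas, walks, frames, and sensor traces.

Everything here is a pure function of its seed, so end-to-end tests of the
tracking pipeline and closed-loop controller are bitwise reproducible.  The
generators emulate the modeled platform's behavioral recordings — a dark
(black) mouse against a white background, imaged only in the camera-visible
chambers — and its 20 Hz sensor streams with injectable anomalies.  Arena
defaults scale the physical chambers (14 cm boxes, 20 cm middle chamber)
at 10 px/cm.

The walk model is a reflected correlated random walk (Gaussian heading
noise, constant step length): the simplest motion model that exercises all
chamber-transition paths.  It makes no claim of behavioral realism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .controller import ControllerConfig, SensorThresholds, run_closed_loop
from .errors import ConfigurationError
from .protocol import StimulationProtocol
from .sensors import SENSOR_KINDS
from .tracking import (
    ROI,
    ChamberTimeline,
    DetectionConfig,
    Trajectory,
    binarize,
    centroid,
    classify_light_dark,
    classify_three_chamber,
    count_target_pixels,
)

__all__ = [
    "ArenaSpec",
    "WalkParams",
    "AnomalySpec",
    "WalkResult",
    "RigResult",
    "lightdark_arena",
    "three_chamber_arena",
    "open_field_arena",
    "simulate_walk",
    "render_frames",
    "simulate_sensor_traces",
    "track_frames",
    "virtual_rig",
    "DEFAULT_BASELINES",
]

PX_PER_CM = 10


@dataclass(frozen=True)
class ArenaSpec:
    """Virtual arena: chambers laid out along x, a camera-visible window.

    ``chambers`` maps label -> (x0, x1) pixel intervals (disjoint,
    half-open); ``visible`` is the imaged x-interval (the rendered frame
    spans it at the arena's full height).
    """

    paradigm: str
    chambers: Dict[str, Tuple[int, int]]
    height_px: int
    visible: Tuple[int, int]
    blob_radius_px: int = 15

    def __post_init__(self) -> None:
        spans = sorted(self.chambers.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ConfigurationError("chamber intervals must be disjoint")
        if self.visible[1] <= self.visible[0]:
            raise ConfigurationError("visible region must be non-empty")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError("arena must have positive area")

    @property
    def width_px(self) -> int:
        return max(x1 for _, x1 in self.chambers.values())

    def label_of(self, x: float) -> str:
        for label, (x0, x1) in self.chambers.items():
            if x0 <= x < x1:
                return label
        # walks are confined to the arena; boundary hits land in the last chamber
        return max(self.chambers, key=lambda k: self.chambers[k][1])


def lightdark_arena(px_per_cm: int = PX_PER_CM, blob_radius_px: int = 15) -> ArenaSpec:
    """Two 14 cm chambers; only the light box is imaged."""
    w = 14 * px_per_cm
    return ArenaSpec(
        paradigm="lightdark",
        chambers={"light": (0, w), "dark": (w, 2 * w)},
        height_px=10 * px_per_cm,
        visible=(0, w),
        blob_radius_px=blob_radius_px,
    )


def three_chamber_arena(px_per_cm: int = PX_PER_CM, blob_radius_px: int = 15) -> ArenaSpec:
    """14 cm side chambers flanking a 20 cm middle; middle is imaged."""
    side = 14 * px_per_cm
    mid = 20 * px_per_cm
    return ArenaSpec(
        paradigm="threechamber",
        chambers={
            "left": (0, side),
            "middle": (side, side + mid),
            "right": (side + mid, 2 * side + mid),
        },
        height_px=10 * px_per_cm,
        visible=(side, side + mid),
        blob_radius_px=blob_radius_px,
    )


def open_field_arena(px_per_cm: int = PX_PER_CM, blob_radius_px: int = 15) -> ArenaSpec:
    """Single fully imaged 14 x 10 cm box for locomotion analysis."""
    return ArenaSpec(
        paradigm="openfield",
        chambers={"arena": (0, 14 * px_per_cm)},
        height_px=10 * px_per_cm,
        visible=(0, 14 * px_per_cm),
        blob_radius_px=blob_radius_px,
    )


@dataclass(frozen=True)
class WalkParams:
    """Reflected correlated random walk parameters."""

    seed: int = 0
    steps: int = 600
    dt: float = 0.05
    mean_speed_px: float = 8.0
    turning_noise: float = 0.4
    start: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.mean_speed_px < 0:
            raise ConfigurationError("mean speed must be >= 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.steps < 1:
            raise ConfigurationError("steps must be >= 1")


@dataclass(frozen=True)
class AnomalySpec:
    """Additive sensor disturbance over a time window."""

    kind: str
    onset: float
    duration: float
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in SENSOR_KINDS:
            raise ConfigurationError(f"unknown sensor kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0:
            raise ConfigurationError("anomaly needs onset >= 0 and duration > 0")


@dataclass
class WalkResult:
    positions: np.ndarray  # (steps, 2) float px
    labels: List[str]
    dt: float


def simulate_walk(arena: ArenaSpec, params: WalkParams) -> WalkResult:
    """Ground-truth trajectory plus per-frame chamber labels.

    The walk reflects off the arena walls with a margin of one blob radius,
    so the rendered blob always stays inside the arena.
    """
    rng = np.random.default_rng(params.seed)
    margin = float(arena.blob_radius_px)
    lo = np.array([margin, margin])
    hi = np.array([arena.width_px - margin, arena.height_px - margin])
    if np.any(hi <= lo):
        raise ConfigurationError("arena too small for the blob radius")

    pos = (
        np.array(params.start, dtype=float)
        if params.start is not None
        else (lo + hi) / 2.0
    )
    heading = rng.uniform(0, 2 * math.pi)
    out = np.empty((params.steps, 2))
    labels: List[str] = []
    for i in range(params.steps):
        out[i] = pos
        labels.append(arena.label_of(pos[0]))
        heading += rng.normal(0.0, params.turning_noise)
        step = params.mean_speed_px * np.array([math.cos(heading), math.sin(heading)])
        pos = pos + step
        # reflect off each wall (repeat in case a long step crosses twice)
        for axis in range(2):
            for _ in range(4):
                if pos[axis] < lo[axis]:
                    pos[axis] = 2 * lo[axis] - pos[axis]
                    heading = (math.pi - heading) if axis == 0 else -heading
                elif pos[axis] > hi[axis]:
                    pos[axis] = 2 * hi[axis] - pos[axis]
                    heading = (math.pi - heading) if axis == 0 else -heading
                else:
                    break
            pos[axis] = min(max(pos[axis], lo[axis]), hi[axis])
    return WalkResult(positions=out, labels=labels, dt=params.dt)


def render_frames(
    positions: np.ndarray,
    arena: ArenaSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> List[np.ndarray]:
    """Render the camera view: white background, black disc at each position.

    Only the visible window is rendered; a blob outside it leaves a blank
    frame.  Optional i.i.d. Gaussian pixel noise is clipped to [0, 255].
    """
    x0, x1 = arena.visible
    w = x1 - x0
    h = arena.height_px
    r = arena.blob_radius_px
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:h, 0:w]
    frames = []
    for px, py in np.atleast_2d(positions):
        frame = np.full((h, w), 255, dtype=float)
        cx = px - x0
        if -r <= cx < w + r:
            frame[(xs - cx) ** 2 + (ys - py) ** 2 <= r * r] = 0
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append(np.clip(frame, 0, 255).astype(np.uint8))
    return frames


DEFAULT_BASELINES = {
    "magnetic": 0.0,  # mT, field off between stimulation windows
    "temperature": 24.0,  # degC room temperature
    "sound": 45.0,  # dB ambient
    "vibration": 0.02,  # g resting rig
}


def simulate_sensor_traces(
    duration: float,
    poll_rate: float = 20.0,
    baselines: Optional[Dict[str, float]] = None,
    noise_sd: float | Dict[str, float] = 0.0,
    anomalies: Sequence[AnomalySpec] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-kind baseline + seeded Gaussian noise + additive anomalies.

    Returns a long-format stream (time_s, kind, value) with
    ``ceil(duration * poll_rate)`` samples per kind.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    base = dict(DEFAULT_BASELINES)
    if baselines:
        base.update(baselines)
    n = math.ceil(duration * poll_rate - 1e-9)
    t = np.arange(n) / poll_rate
    rng = np.random.default_rng(seed)
    for a in anomalies:
        if a.onset >= duration:
            warnings.warn(
                f"anomaly on {a.kind} at t={a.onset} s starts after the "
                f"{duration} s trace; clipped away",
                stacklevel=2,
            )
    parts = []
    for kind in SENSOR_KINDS:
        sd = noise_sd.get(kind, 0.0) if isinstance(noise_sd, dict) else noise_sd
        values = np.full(n, base[kind], dtype=float)
        if sd > 0:
            values += rng.normal(0.0, sd, size=n)
        for a in anomalies:
            if a.kind == kind:
                values[(t >= a.onset) & (t < a.onset + a.duration)] += a.magnitude
        parts.append(pd.DataFrame({"time_s": t, "kind": kind, "value": values}))
    return pd.concat(parts, ignore_index=True)


def track_frames(
    frames: Sequence[np.ndarray],
    arena: ArenaSpec,
    detection: DetectionConfig,
    roi_width: Optional[int] = None,
) -> Tuple[List[str], Trajectory, List[int]]:
    """Run the paradigm's tracking algorithm over rendered frames.

    Returns (chamber labels, centroid trajectory in frame pixels, raw
    target-pixel counts — for three-chamber, the per-frame max of the two
    ROI counts).
    """
    h = arena.height_px
    w = arena.visible[1] - arena.visible[0]
    if roi_width is None:
        roi_width = w // 2  # two ROIs tiling the imaged middle chamber
    labels: List[str] = []
    points: List[Optional[Tuple[float, float]]] = []
    counts: List[int] = []
    state = "unknown"
    full = ROI(0, 0, w, h)
    roi_l = ROI(0, 0, min(roi_width, w), h)
    roi_r = ROI(max(0, w - roi_width), 0, min(roi_width, w), h)
    for frame in frames:
        if arena.paradigm == "threechamber":
            c_l = count_target_pixels(binarize(frame, roi_l, detection), detection.target_color)
            c_r = count_target_pixels(binarize(frame, roi_r, detection), detection.target_color)
            chamber, state = classify_three_chamber(
                c_l,
                c_r,
                (detection.pixel_count_threshold, detection.pixel_count_threshold),
                state,
            )
            counts.append(max(c_l, c_r))
        else:
            mask = binarize(frame, full, detection)
            n = count_target_pixels(mask, detection.target_color)
            counts.append(n)
            if arena.paradigm == "lightdark":
                chamber = classify_light_dark(n, detection.pixel_count_threshold)
            else:
                chamber = "arena"
        labels.append(chamber)
        points.append(centroid(binarize(frame, full, detection), detection.target_color))
    traj = Trajectory(points=points, scale_mm_per_px=1.0, fps=1.0)
    return labels, traj, counts


@dataclass
class RigResult:
    """Everything a virtual experiment produced, plus its ground truth."""

    log: pd.DataFrame
    measured_labels: List[str]
    truth_labels: List[str]
    trajectory: Trajectory
    position_stream: pd.DataFrame
    sensor_stream: pd.DataFrame


def virtual_rig(
    protocol: StimulationProtocol,
    arena: ArenaSpec,
    walk: WalkParams,
    thresholds: SensorThresholds,
    config: ControllerConfig = ControllerConfig(),
    detection: DetectionConfig = DetectionConfig(pixel_count_threshold=50),
    anomalies: Sequence[AnomalySpec] = (),
    target_chamber: str = "dark",
    noise_sd: float = 0.0,
    sensor_noise_sd: float = 0.0,
) -> RigResult:
    """Wire walk -> frames -> tracking -> controller into one virtual run.

    The walk is sampled at the controller poll rate over the protocol
    duration (``walk.steps`` and ``walk.dt`` are overridden accordingly).
    """
    duration = float(protocol.duration)
    dt = 1.0 / config.sensor_poll_rate
    steps = math.ceil(duration * config.sensor_poll_rate - 1e-9)
    walk = WalkParams(
        seed=walk.seed,
        steps=steps,
        dt=dt,
        mean_speed_px=walk.mean_speed_px,
        turning_noise=walk.turning_noise,
        start=walk.start,
    )
    truth = simulate_walk(arena, walk)
    frames = render_frames(truth.positions, arena, noise_sd=noise_sd, seed=walk.seed + 1)
    measured, traj, _ = track_frames(frames, arena, detection)
    times = np.arange(steps) * dt
    position_stream = pd.DataFrame(
        {
            "time_s": times,
            "chamber": measured,
            "in_target": [m == target_chamber for m in measured],
        }
    )
    sensor_stream = simulate_sensor_traces(
        duration,
        poll_rate=config.sensor_poll_rate,
        noise_sd=sensor_noise_sd,
        anomalies=anomalies,
        seed=walk.seed + 2,
    )
    traj = Trajectory(points=traj.points, scale_mm_per_px=1.0, fps=1.0 / dt)
    log = run_closed_loop(protocol, sensor_stream, position_stream, thresholds, config)
    return RigResult(
        log=log,
        measured_labels=measured,
        truth_labels=truth.labels,
        trajectory=traj,
        position_stream=position_stream,
        sensor_stream=sensor_stream,
    )
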