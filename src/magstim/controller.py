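"""Closed-loop stimulation engine with three-gate control.

The engine applies the alternating magnetic field only when, at a poll
instant, all three gating conditions hold:

1. the stimulation protocol is in a programmed ON interval,
2. every enabled sensor reading is within its preset thresholds, and
3. the subject is inside the target stimulation area (video tracking).

Gates are evaluated at poll instants (20 Hz by default), so the latency
from a threshold breach to stimulation-off is bounded by one poll interval.
Thresholds are inclusive: a reading exactly at the limit counts as a
breach.  A sensor whose most recent reading is older than two poll
intervals is considered stale and fails the sensor gate (fail-safe).  With
``breach_action="pause"`` stimulation resumes as soon as readings return
within limits and the other gates hold; ``"abort"`` latches stimulation off
for the rest of the run.

Experiment logs are plain CSV, one row per poll.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MagstimError, StreamTruncationError
from .protocol import StimulationProtocol, protocol_timeline
from .sensors import SENSOR_KINDS, SENSOR_TABLE

__all__ = [
    "ThresholdSpec",
    "SensorThresholds",
    "GateSnapshot",
    "ControllerConfig",
    "evaluate_gates",
    "run_closed_loop",
    "write_log",
    "read_log",
    "LOG_COLUMNS",
]

LOG_COLUMNS = [
    "time_s",
    "mf_mT",
    "temp_C",
    "sound_dB",
    "accel_g",
    "stim_state",
    "chamber",
    "in_target",
]

_LOG_KIND_COLUMN = {
    "magnetic": "mf_mT",
    "temperature": "temp_C",
    "sound": "sound_dB",
    "vibration": "accel_g",
}


@dataclass(frozen=True)
class ThresholdSpec:
    """Gating limits of one sensor kind.

    ``upper`` is the breach limit (reading >= upper breaches); ``lower``
    is optional (reading <= lower breaches) and is typically used for the
    signed magnetic reading.
    """

    enabled: bool = True
    upper: Optional[float] = None
    lower: Optional[float] = None

    def breached(self, value: float) -> bool:
        if not self.enabled:
            return False
        if self.upper is not None and value >= self.upper:
            return True
        if self.lower is not None and value <= self.lower:
            return True
        return False


@dataclass(frozen=True)
class SensorThresholds:
    """Per-kind threshold table; limits must lie in the detection ranges."""

    limits: Dict[str, ThresholdSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind, spec in self.limits.items():
            if kind not in SENSOR_KINDS:
                raise ConfigurationError(f"unknown sensor kind {kind!r}")
            lo, hi = SENSOR_TABLE[kind].detection_range
            for limit in (spec.upper, spec.lower):
                if limit is not None and not lo <= limit <= hi:
                    raise ConfigurationError(
                        f"{kind} threshold {limit} outside detection range [{lo}, {hi}]"
                    )

    def spec(self, kind: str) -> ThresholdSpec:
        return self.limits.get(kind, ThresholdSpec(enabled=False))


@dataclass(frozen=True)
class GateSnapshot:
    time: float
    protocol_on: bool
    sensors_ok: bool
    in_target: bool


@dataclass(frozen=True)
class ControllerConfig:
    """Sampling and breach policy of the closed-loop engine."""

    sensor_poll_rate: float = 20.0
    extra_reads_per_cycle: int = 2
    breach_action: str = "pause"

    def __post_init__(self) -> None:
        if self.sensor_poll_rate <= 0:
            raise ConfigurationError("sensor_poll_rate must be > 0")
        if self.breach_action not in ("pause", "abort"):
            raise ConfigurationError("breach_action must be 'pause' or 'abort'")


def evaluate_gates(snapshot: GateSnapshot) -> bool:
    """Stimulate iff protocol ON and sensors OK and subject in target."""
    return snapshot.protocol_on and snapshot.sensors_ok and snapshot.in_target


class _Stream:
    """Sorted time-indexed lookup of the most recent row at or before t."""

    def __init__(self, times: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        order = np.argsort(self.times, kind="stable")
        self.order = order
        self.sorted_times = self.times[order]

    def latest(self, t: float) -> Optional[int]:
        idx = int(np.searchsorted(self.sorted_times, t, side="right")) - 1
        if idx < 0:
            return None
        return int(self.order[idx])


def run_closed_loop(
    protocol: StimulationProtocol,
    sensor_stream: pd.DataFrame,
    position_stream: pd.DataFrame,
    thresholds: SensorThresholds,
    config: ControllerConfig = ControllerConfig(),
) -> pd.DataFrame:
    """Simulate the closed loop over recorded streams; returns the log.

    ``sensor_stream`` columns: time_s, kind, value.  ``position_stream``
    columns: time_s, chamber, in_target.  Both must cover the protocol
    duration.  The output is one row per poll with the latest sensor
    values, the commanded stimulation state, and the gate inputs.
    """
    duration = float(protocol.duration)
    n_polls = math.ceil(duration * config.sensor_poll_rate - 1e-9)
    poll_dt = 1.0 / config.sensor_poll_rate
    last_poll = (n_polls - 1) * poll_dt if n_polls else 0.0

    for name, stream, col in (
        ("sensor stream", sensor_stream, "time_s"),
        ("position stream", position_stream, "time_s"),
    ):
        if len(stream) == 0 or stream[col].max() < last_poll - poll_dt:
            raise StreamTruncationError(
                f"{name} ends before the protocol duration ({duration:g} s)"
            )

    on_windows = [(float(s), float(e)) for s, e, on in protocol_timeline(protocol) if on]
    starts = np.array([w[0] for w in on_windows])
    ends = np.array([w[1] for w in on_windows])

    kind_streams = {}
    for kind in SENSOR_KINDS:
        sub = sensor_stream[sensor_stream["kind"] == kind]
        kind_streams[kind] = (
            _Stream(sub["time_s"].to_numpy()),
            sub["value"].to_numpy(),
        )
    pos_lookup = _Stream(position_stream["time_s"].to_numpy())
    pos_chamber = position_stream["chamber"].to_numpy()
    pos_target = position_stream["in_target"].to_numpy()

    stale_after = 2.0 * poll_dt
    aborted = False
    rows = []
    for k in range(n_polls):
        t = k * poll_dt
        idx = int(np.searchsorted(starts, t, side="right")) - 1
        protocol_on = idx >= 0 and t < ends[idx]

        sensors_ok = True
        values = {}
        for kind in SENSOR_KINDS:
            lookup, vals = kind_streams[kind]
            i = lookup.latest(t)
            spec = thresholds.spec(kind)
            if i is None:
                values[kind] = math.nan
                if spec.enabled:
                    sensors_ok = False  # no reading yet: fail safe
                continue
            value = float(vals[i])
            values[kind] = value
            if spec.enabled and t - float(lookup.times[i]) > stale_after + 1e-12:
                sensors_ok = False  # stale reading: fail safe
            elif spec.breached(value):
                sensors_ok = False

        if not sensors_ok and config.breach_action == "abort":
            aborted = True

        j = pos_lookup.latest(t)
        chamber = str(pos_chamber[j]) if j is not None else "unknown"
        in_target = bool(pos_target[j]) if j is not None else False

        stim = (
            evaluate_gates(
                GateSnapshot(
                    time=t,
                    protocol_on=bool(protocol_on),
                    sensors_ok=sensors_ok,
                    in_target=in_target,
                )
            )
            and not aborted
        )
        rows.append(
            {
                "time_s": t,
                "mf_mT": values["magnetic"],
                "temp_C": values["temperature"],
                "sound_dB": values["sound"],
                "accel_g": values["vibration"],
                "stim_state": "on" if stim else "off",
                "chamber": chamber,
                "in_target": bool(in_target),
            }
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(log: pd.DataFrame, path) -> None:
    """Write an experiment log as CSV (lossless round trip)."""
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ConfigurationError(f"log lacks columns {missing}")
    log.to_csv(path, index=False)


def read_log(path) -> pd.DataFrame:
    """Read and validate an experiment log CSV."""
    try:
        log = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise MagstimError(f"malformed experiment log {path}: {exc}") from exc
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise MagstimError(f"experiment log {path} lacks columns {missing}")
    times = log["time_s"].to_numpy()
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise MagstimError(
            f"experiment log {path}: time not strictly increasing at row {bad[0] + 3}"
        )
    if not set(log["stim_state"].unique()) <= {"on", "off"}:
        raise MagstimError(f"experiment log {path}: stim_state must be 'on' or 'off'")
    log["in_target"] = log["in_target"].astype(bool)
    return log
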