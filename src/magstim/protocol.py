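"""Stimulation-protocol compiler with H-bridge safety semantics.

A protocol is an ordered list of phases, each a (stimulation, rest) pair
with a square-wave frequency, an H-bridge dead time, and a repeat count.
Compilation turns a phase table into a per-channel timeline of pin-pair
events for an H-bridge driver:

* **bidirectional** mode alternates the forward (pin A high) and reverse
  (pin B high) directions every half-period, inserting a both-pins-low dead
  time of ``dead_time`` seconds before every direction change so the two
  half-bridge legs can never cross-conduct (shoot-through).
* **unidirectional** mode emits an on/off square wave at 50% duty.
* rest periods are all-off.

Phases begin with their stimulation period, then rest.  Event times are
exact rationals (``fractions.Fraction``) of the input durations, so long
protocols accumulate no floating-point drift; they are emitted as float
seconds only on export.

With all sensor detection features active the firmware this models keeps
stable signal timing below 200 Hz; above that the per-cycle sensor reads
perturb output timing unless sensing is disabled.  ``validate_protocol``
encodes that feasibility rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Sequence, Union

import pandas as pd

from .errors import ProtocolError

__all__ = [
    "ProtocolPhase",
    "StimulationProtocol",
    "HBridgeState",
    "WaveformEvent",
    "TimingReport",
    "compile_waveform",
    "validate_protocol",
    "protocol_timeline",
    "energized_time",
    "timeline_from_events",
    "export_waveform",
    "load_protocol",
    "save_protocol",
]

#: above this square-wave frequency the modeled firmware cannot hold timing
#: while sensor detection is active (strict inequality: 200 Hz itself fails)
SENSING_MAX_HZ = 200.0
#: supported hardware range with sensing disabled
HARDWARE_MAX_HZ = 1000.0

OFF = None  # sentinel readability only

Number = Union[int, float, Fraction]


def _frac(x: Number) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x)


@dataclass(frozen=True)
class ProtocolPhase:
    """One row of the protocol table.

    ``stim_duration`` / ``rest_duration`` in seconds, ``frequency`` in Hz,
    ``dead_time`` in seconds (must be below the half-period),
    ``mode`` is ``"bidirectional"`` or ``"unidirectional"``.
    """

    stim_duration: Number
    rest_duration: Number
    frequency: Number = 10.0
    dead_time: Number = 0.001
    mode: str = "bidirectional"
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.stim_duration < 0 or self.rest_duration < 0:
            raise ProtocolError("phase durations must be >= 0")
        if self.stim_duration > 0 and self.frequency <= 0:
            raise ProtocolError("frequency must be > 0 when stimulating")
        if self.repeats < 1:
            raise ProtocolError("repeats must be >= 1")
        if self.mode not in ("bidirectional", "unidirectional"):
            raise ProtocolError(f"unknown mode {self.mode!r}")
        if self.dead_time < 0:
            raise ProtocolError("dead_time must be >= 0")
        if self.stim_duration > 0 and _frac(self.dead_time) >= self.half_period:
            raise ProtocolError(
                f"dead_time {self.dead_time} s must be below the half-period "
                f"{float(self.half_period)} s at {self.frequency} Hz"
            )

    @property
    def half_period(self) -> Fraction:
        return 1 / (2 * _frac(self.frequency))

    @property
    def duration(self) -> Fraction:
        return self.repeats * (_frac(self.stim_duration) + _frac(self.rest_duration))


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered phase table targeting up to six H-bridge channels."""

    phases: Sequence[ProtocolPhase]
    channel_count: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.channel_count <= 6:
            raise ProtocolError("channel_count must be between 1 and 6")

    @property
    def duration(self) -> Fraction:
        return sum((p.duration for p in self.phases), Fraction(0))


@dataclass(frozen=True)
class HBridgeState:
    """Pin pair of one H-bridge channel; both-high is unrepresentable-invalid."""

    pin_a: bool = False
    pin_b: bool = False

    def __post_init__(self) -> None:
        if self.pin_a and self.pin_b:
            raise ProtocolError("pin_a and pin_b may never be simultaneously high")

    @property
    def direction(self) -> str:
        if self.pin_a:
            return "forward"
        if self.pin_b:
            return "reverse"
        return "off"


FORWARD = HBridgeState(pin_a=True)
REVERSE = HBridgeState(pin_b=True)
ALL_OFF = HBridgeState()


@dataclass(frozen=True)
class WaveformEvent:
    """State change of one channel at an instant (time in exact seconds)."""

    time: Fraction
    channel: int
    state: HBridgeState


@dataclass(frozen=True)
class TimingReport:
    frequency: float
    sensing_enabled: bool
    feasible: bool
    note: str = ""


def compile_waveform(protocol: StimulationProtocol, channel: int = 0) -> List[WaveformEvent]:
    """Compile the protocol into the pin-pair event timeline of one channel.

    Events are emitted only on state changes and are strictly increasing in
    time; the timeline starts and ends all-off.
    """
    if not 0 <= channel < protocol.channel_count:
        raise ProtocolError(
            f"channel {channel} out of range for {protocol.channel_count} channels"
        )
    raw: List[tuple] = [(Fraction(0), ALL_OFF)]
    t = Fraction(0)
    for phase in protocol.phases:
        stim = _frac(phase.stim_duration)
        rest = _frac(phase.rest_duration)
        for _ in range(phase.repeats):
            if stim > 0:
                raw.extend(_compile_stim_window(phase, t, t + stim))
                raw.append((t + stim, ALL_OFF))
            t += stim + rest
    raw.append((t, ALL_OFF))

    # collapse same-instant entries (last wins) and drop no-change events
    events: List[WaveformEvent] = []
    state = ALL_OFF
    i = 0
    while i < len(raw):
        j = i
        while j + 1 < len(raw) and raw[j + 1][0] == raw[i][0]:
            j += 1
        time, new_state = raw[j]
        if new_state != state or not events:
            events.append(WaveformEvent(time=time, channel=channel, state=new_state))
            state = new_state
        i = j + 1
    return events


def _compile_stim_window(phase: ProtocolPhase, start: Fraction, end: Fraction):
    half = phase.half_period
    dead = _frac(phase.dead_time)
    out = []
    if phase.mode == "bidirectional":
        hold = half - dead
        cur = start
        direction = FORWARD
        while cur < end:
            out.append((cur, direction))
            out.append((min(cur + hold, end), ALL_OFF))
            cur += half
            direction = REVERSE if direction is FORWARD else FORWARD
    else:  # unidirectional: 50% duty on/off square wave
        cur = start
        while cur < end:
            out.append((cur, FORWARD))
            out.append((min(cur + half, end), ALL_OFF))
            cur += 2 * half
    return out


def validate_protocol(
    protocol: StimulationProtocol, sensing_enabled: bool = True
) -> TimingReport:
    """Check timing feasibility of the protocol's fastest phase."""
    freqs = [float(p.frequency) for p in protocol.phases if p.stim_duration > 0]
    fmax = max(freqs, default=0.0)
    if sensing_enabled:
        feasible = fmax < SENSING_MAX_HZ
        note = (
            ""
            if feasible
            else (
                f"{fmax:g} Hz exceeds the stable range with sensor detection "
                f"active (< {SENSING_MAX_HZ:g} Hz); per-cycle sensor reads "
                "perturb output timing. Disable sensing or lower the frequency."
            )
        )
    else:
        feasible = fmax <= HARDWARE_MAX_HZ
        note = (
            ""
            if feasible
            else f"{fmax:g} Hz exceeds the supported hardware range ({HARDWARE_MAX_HZ:g} Hz)"
        )
    return TimingReport(
        frequency=fmax, sensing_enabled=sensing_enabled, feasible=feasible, note=note
    )


def protocol_timeline(protocol: StimulationProtocol) -> List[tuple]:
    """Intended-ON timeline: (start, end, stim_on) covering the protocol.

    A partition of [0, duration): total ON time equals
    sum(stim_duration * repeats).
    """
    out: List[tuple] = []
    t = Fraction(0)

    def push(start: Fraction, end: Fraction, on: bool) -> None:
        if end <= start:
            return
        if out and out[-1][2] == on and out[-1][1] == start:
            out[-1] = (out[-1][0], end, on)
        else:
            out.append((start, end, on))

    for phase in protocol.phases:
        stim = _frac(phase.stim_duration)
        rest = _frac(phase.rest_duration)
        for _ in range(phase.repeats):
            push(t, t + stim, True)
            push(t + stim, t + stim + rest, False)
            t += stim + rest
    return out


def energized_time(events: Sequence[WaveformEvent]) -> Fraction:
    """Total time with either pin high, from a compiled event timeline."""
    total = Fraction(0)
    for prev, nxt in zip(events, events[1:]):
        if prev.state.direction != "off":
            total += nxt.time - prev.time
    return total


def timeline_from_events(
    events: Sequence[WaveformEvent], max_gap: Number
) -> List[tuple]:
    """Reconstruct ON windows from events, merging drive gaps <= ``max_gap``.

    Inverse of compilation for protocols whose rest periods exceed
    ``max_gap`` (use the phase's period + dead time as the merge width).
    """
    gap = _frac(max_gap)
    windows: List[tuple] = []
    on_since = None
    last_off = None
    for prev, nxt in zip(events, events[1:]):
        if prev.state.direction == "off":
            continue
        start, end = prev.time, nxt.time
        if on_since is None:
            on_since, last_off = start, end
        elif start - last_off <= gap:
            last_off = end
        else:
            windows.append((on_since, last_off, True))
            on_since, last_off = start, end
    if on_since is not None:
        windows.append((on_since, last_off, True))
    return windows


def export_waveform(events: Sequence[WaveformEvent], path) -> None:
    """Write events as CSV (time_s, channel, pin_a, pin_b), float seconds."""
    df = pd.DataFrame(
        {
            "time_s": [float(e.time) for e in events],
            "channel": [e.channel for e in events],
            "pin_a": [int(e.state.pin_a) for e in events],
            "pin_b": [int(e.state.pin_b) for e in events],
        }
    )
    df.to_csv(path, index=False)


_PHASE_COLUMNS = ["stim_s", "rest_s", "frequency_hz", "dead_time_s", "mode", "repeats"]


def save_protocol(protocol: StimulationProtocol, path) -> None:
    """Write the phase table as CSV mirroring the protocol-page columns."""
    df = pd.DataFrame(
        [
            {
                "stim_s": float(p.stim_duration),
                "rest_s": float(p.rest_duration),
                "frequency_hz": float(p.frequency),
                "dead_time_s": float(p.dead_time),
                "mode": p.mode,
                "repeats": p.repeats,
            }
            for p in protocol.phases
        ]
    )
    df.to_csv(path, index=False)


def load_protocol(path, channel_count: int = 1) -> StimulationProtocol:
    """Read a phase table written by :func:`save_protocol` (or hand-edited)."""
    df = pd.read_csv(path)
    missing = [c for c in _PHASE_COLUMNS if c not in df.columns]
    if missing:
        raise ProtocolError(f"protocol file {path} lacks columns {missing}")
    phases = [
        ProtocolPhase(
            stim_duration=row.stim_s,
            rest_duration=row.rest_s,
            frequency=row.frequency_hz,
            dead_time=row.dead_time_s,
            mode=row.mode,
            repeats=int(row.repeats),
        )
        for row in df.itertuples()
    ]
    return StimulationProtocol(phases=phases, channel_count=channel_count)
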