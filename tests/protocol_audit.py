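"""Independent audit of compiled H-bridge event timelines.

Re-derives safety properties (shoot-through, dead-time gaps, energized
time) directly from the event list, without reusing the compiler's
bookkeeping.
"""

from __future__ import annotations

from fractions import Fraction


def audit_events(events):
    """Scan a compiled timeline; returns a dict of audited properties.

    * ``both_high``: count of events with both pins high (must be 0).
    * ``min_opposite_gap``: smallest off-gap between a direction's falling
      edge and the opposite direction's rising edge (None if no reversal).
    * ``energized``: exact total time with either pin high.
    * ``monotone``: whether event times are strictly increasing.
    """
    both_high = 0
    energized = Fraction(0)
    min_gap = None
    monotone = True
    last_dir = None
    last_off_time = None
    prev_time = None
    prev_state = None
    for ev in events:
        if ev.state.pin_a and ev.state.pin_b:
            both_high += 1
        if prev_time is not None:
            if ev.time <= prev_time:
                monotone = False
            if prev_state is not None and prev_state.direction != "off":
                energized += ev.time - prev_time
        direction = ev.state.direction
        if direction == "off" and prev_state is not None and prev_state.direction != "off":
            last_dir = prev_state.direction
            last_off_time = ev.time
        elif direction != "off" and last_dir is not None and direction != last_dir:
            gap = ev.time - last_off_time
            if min_gap is None or gap < min_gap:
                min_gap = gap
        prev_time = ev.time
        prev_state = ev.state
    return {
        "both_high": both_high,
        "min_opposite_gap": min_gap,
        "energized": energized,
        "monotone": monotone,
    }


def random_protocol(rng):
    """Random single-phase protocol with exactly-representable timing.

    Durations are integer multiples of the period so the expected
    energized time has an exact closed form:
    bidirectional -> stim - n_half * dead; unidirectional -> stim / 2.
    """
    from magstim.protocol import ProtocolPhase, StimulationProtocol

    freq = Fraction(int(rng.choice([1, 2, 5, 10, 20, 50, 100, 199])))
    periods = int(rng.integers(1, 12))
    stim = periods / freq
    half = 1 / (2 * freq)
    dead = half * Fraction(int(rng.integers(0, 40)), 100)
    mode = "bidirectional" if rng.random() < 0.7 else "unidirectional"
    rest = Fraction(int(rng.integers(0, 5)))
    repeats = int(rng.integers(1, 4))
    phase = ProtocolPhase(
        stim_duration=stim,
        rest_duration=rest,
        frequency=freq,
        dead_time=dead,
        mode=mode,
        repeats=repeats,
    )
    n_half = periods * 2
    if mode == "bidirectional":
        expected = repeats * (stim - n_half * dead)
    else:
        expected = repeats * stim / 2
    return StimulationProtocol(phases=[phase]), phase, expected
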