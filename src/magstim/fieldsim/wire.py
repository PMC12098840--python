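"""Winding-level engineering estimates: wire resistance and inductance.

These are nominal estimators (room-temperature AWG copper tables and
Wheeler's multilayer approximation), useful for sanity-checking a coil
design against a bench measurement; they carry no claim of as-built
accuracy.
"""

from __future__ import annotations

import math

from ..errors import ConfigurationError
from .coils import CoilSpec

__all__ = ["AWG_OHMS_PER_M", "estimate_resistance", "estimate_inductance", "wire_length"]

#: nominal resistance of solid copper wire at 20 C, ohms per meter
AWG_OHMS_PER_M = {
    10: 0.003277,
    12: 0.005211,
    14: 0.008286,
    16: 0.01317,
    18: 0.02095,
    20: 0.03331,
    22: 0.05296,
    24: 0.08422,
    26: 0.1339,
    28: 0.2129,
    30: 0.3386,
}


def wire_length(coil: CoilSpec) -> float:
    """Total wire length: turns x mean-turn circumference, meters."""
    return coil.turns * 2.0 * math.pi * coil.mean_radius


def estimate_resistance(coil: CoilSpec) -> float:
    """DC resistance of the winding in ohms, from the nominal AWG table."""
    if coil.wire_gauge is None:
        raise ConfigurationError("coil has no wire_gauge set; resistance needs one")
    try:
        per_m = AWG_OHMS_PER_M[coil.wire_gauge]
    except KeyError:
        raise ConfigurationError(
            f"unknown wire gauge {coil.wire_gauge} AWG; supported: "
            f"{sorted(AWG_OHMS_PER_M)}"
        ) from None
    return wire_length(coil) * per_m


def estimate_inductance(coil: CoilSpec) -> float:
    """Wheeler's multilayer air-coil approximation, henries.

    L [uH] = 31.6 * N^2 * a^2 / (6a + 9b + 10c) with mean radius ``a``,
    axial length ``b``, radial build ``c`` in meters.
    """
    a = coil.mean_radius
    b = coil.axial_length
    c = coil.radial_build
    l_uh = 31.6 * coil.turns**2 * a * a / (6 * a + 9 * b + 10 * c)
    return l_uh * 1e-6
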