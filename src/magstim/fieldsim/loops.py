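"""Exact magnetostatics of circular current loops.

The field of a filamentary circular loop has a closed form in the complete
elliptic integrals K and E (Smythe, *Static and Dynamic Electricity*).  With
the loop of radius ``R`` carrying current ``I`` in the plane ``z = z0`` and a
field point at cylindrical coordinates ``(r, z)``::

    alpha^2 = R^2 + r^2 + (z-z0)^2 - 2 R r
    beta^2  = R^2 + r^2 + (z-z0)^2 + 2 R r
    m       = 1 - alpha^2 / beta^2          (elliptic parameter, m = k^2)

    B_z = mu0 I / (2 pi alpha^2 beta) * [ (R^2 - r^2 - dz^2) E(m) + alpha^2 K(m) ]
    B_r = mu0 I dz / (2 pi alpha^2 beta r) * [ (R^2 + r^2 + dz^2) E(m) - alpha^2 K(m) ]

``alpha -> 0`` is the filament itself, where the field diverges.  On the axis
(``r = 0``) the radial component vanishes identically and B_z reduces to the
textbook ``mu0 I R^2 / 2 (R^2 + dz^2)^{3/2}``.

Positive current is counterclockwise viewed from +z, giving ``B_z > 0`` at the
loop center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe, ellipk

from ..constants import MU_0
from ..errors import ConfigurationError, FieldSingularityError

__all__ = ["LoopSpec", "loop_field"]

#: points with alpha^2 closer than this (relative to R^2) to the filament
#: are treated as singular
_SINGULAR_RTOL = 1e-12


@dataclass(frozen=True)
class LoopSpec:
    """A filamentary circular loop coaxial with z.

    Parameters are SI: radius in meters, current in amperes, ``z_position``
    is the axial position of the loop plane.
    """

    radius: float
    current: float
    z_position: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError(f"loop radius must be > 0, got {self.radius}")


def loop_field(loop: LoopSpec, r, z):
    """Field (B_r, B_z) in tesla of a circular loop at cylindrical points.

    ``r`` and ``z`` may be scalars or broadcastable arrays; ``r >= 0``.
    Raises :class:`FieldSingularityError` if any point lies on the filament.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(r < 0):
        raise ConfigurationError("cylindrical radius r must be >= 0")

    R = loop.radius
    dz = z - loop.z_position
    alpha2 = R * R + r * r + dz * dz - 2.0 * R * r
    beta2 = R * R + r * r + dz * dz + 2.0 * R * r
    if np.any(alpha2 <= _SINGULAR_RTOL * R * R):
        raise FieldSingularityError(
            "field point lies on (or numerically on) the loop filament"
        )
    beta = np.sqrt(beta2)
    m = 1.0 - alpha2 / beta2
    K = ellipk(m)
    E = ellipe(m)

    c = MU_0 * loop.current / (2.0 * np.pi)
    Bz = c / (alpha2 * beta) * ((R * R - r * r - dz * dz) * E + alpha2 * K)
    # B_r ~ r near the axis; guard the 1/r with a masked divide
    safe_r = np.where(r > 0, r, 1.0)
    Br = np.where(
        r > 0,
        c * dz / (alpha2 * beta * safe_r) * ((R * R + r * r + dz * dz) * E - alpha2 * K),
        0.0,
    )
    return Br, Bz
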