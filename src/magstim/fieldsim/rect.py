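"""Rectangular (cuboid) air-core coils via finite straight segments.

Each turn is modeled as a rectangular filament loop; every straight segment
contributes through the exact finite-segment Biot-Savart formula in the
numerically robust Hanson-Hirshman form: with ``r1`` and ``r2`` the vectors
from the segment endpoints to the field point,

    B = mu0 I / (4 pi) * (|r1| + |r2|) / (|r1| |r2| (|r1| |r2| + r1.r2)) * (r1 x r2)

The winding volume (between the inner and outer rectangular apertures,
spread along the coil length) is discretized into ``n_layers x n_axial``
filament loops with equal current share, analogous to the circular-coil
filament model.

The coil axis is z: loops lie in planes perpendicular to z, with the
rectangle width along x and height along y, centered on the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constants import MU_0
from ..errors import ConfigurationError, FieldSingularityError
from .fieldmap import FieldMap

__all__ = ["RectCoilSpec", "rect_coil_field", "rect_loop_field", "segment_field"]


@dataclass(frozen=True)
class RectCoilSpec:
    """Air-core rectangular cuboid coil.

    ``inner_width``/``inner_height`` are the aperture dimensions,
    ``outer_width``/``outer_height`` the outer winding dimensions, and
    ``length`` the extent along the coil axis (z), all in meters.
    """

    inner_width: float
    inner_height: float
    outer_width: float
    outer_height: float
    length: float
    turns: int
    current: float

    def __post_init__(self) -> None:
        if self.outer_width <= self.inner_width:
            raise ConfigurationError("outer_width must exceed inner_width")
        if self.outer_height <= self.inner_height:
            raise ConfigurationError("outer_height must exceed inner_height")
        if min(self.inner_width, self.inner_height, self.length) <= 0:
            raise ConfigurationError("coil dimensions must be > 0")
        if self.turns < 1:
            raise ConfigurationError("turns must be >= 1")


def segment_field(a: np.ndarray, b: np.ndarray, current: float, points: np.ndarray) -> np.ndarray:
    """Field (N, 3) tesla of a straight segment from ``a`` to ``b``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r1 = pts - np.asarray(a, dtype=float)
    r2 = pts - np.asarray(b, dtype=float)
    n1 = np.linalg.norm(r1, axis=1)
    n2 = np.linalg.norm(r2, axis=1)
    denom = n1 * n2 * (n1 * n2 + np.einsum("ij,ij->i", r1, r2))
    if np.any(denom <= 0) or np.any(n1 == 0) or np.any(n2 == 0):
        raise FieldSingularityError("field point lies on a segment of the wire path")
    factor = MU_0 * current / (4.0 * np.pi) * (n1 + n2) / denom
    return factor[:, None] * np.cross(r1, r2)


def rect_loop_field(
    half_w: float, half_h: float, z0: float, current: float, points: np.ndarray
) -> np.ndarray:
    """Field of one rectangular filament loop in the plane ``z = z0``.

    The loop runs counterclockwise viewed from +z (positive current gives
    ``B_z > 0`` at the center).
    """
    corners = np.array(
        [
            [+half_w, -half_h, z0],
            [+half_w, +half_h, z0],
            [-half_w, +half_h, z0],
            [-half_w, -half_h, z0],
        ]
    )
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    B = np.zeros_like(pts)
    for i in range(4):
        B += segment_field(corners[i], corners[(i + 1) % 4], current, pts)
    return B


def rect_coil_field(
    rect: RectCoilSpec,
    points: np.ndarray,
    n_layers: int = 10,
    n_axial: int = 10,
) -> FieldMap:
    """Field map of the cuboid coil at Cartesian (x, y, z) points."""
    if n_layers < 1 or n_axial < 1:
        raise ConfigurationError("filament discretization density must be >= 1 per axis")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    share = rect.turns * rect.current / (n_layers * n_axial)
    B = np.zeros_like(pts)
    t = (np.arange(n_layers) + 0.5) / n_layers
    half_ws = (rect.inner_width + t * (rect.outer_width - rect.inner_width)) / 2.0
    half_hs = (rect.inner_height + t * (rect.outer_height - rect.inner_height)) / 2.0
    zs = -rect.length / 2.0 + (np.arange(n_axial) + 0.5) / n_axial * rect.length
    for hw, hh in zip(half_ws, half_hs):
        for z0 in zs:
            B += rect_loop_field(hw, hh, z0, share, pts)
    return FieldMap(points=pts, B=B, coords="xyz")
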