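"""Field maps, evaluation regions, and the homogeneity metric.

Homogeneity of a sampled field over a region is defined as

    homogeneity = (B_max - B_min) / B_mean * 100  [%]

computed over the |B| samples falling inside the region.  It is 0 exactly
when the field is uniform on the region and is invariant under uniform
current scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ..errors import ConfigurationError, EmptyRegionError

__all__ = [
    "FieldMap",
    "RegionSpec",
    "HomogeneityReport",
    "homogeneity",
    "export_field_map",
    "read_field_map",
    "grid_rz",
]


@dataclass(frozen=True)
class RegionSpec:
    """An evaluation region: an axis-aligned cylinder or box.

    ``shape`` is ``"cylinder"`` (radius + height, axis along z) or ``"box"``
    (half_widths, a 3-vector of half-extents).  ``center`` is the region
    center in meters.  For maps sampled in the axisymmetric (r, z) plane the
    cylinder test uses the sample's r directly and the center must lie on
    the axis.
    """

    shape: str
    center: tuple = (0.0, 0.0, 0.0)
    radius: Optional[float] = None
    height: Optional[float] = None
    half_widths: Optional[tuple] = None
    name: str = "region"

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "box"):
            raise ConfigurationError(f"unknown region shape {self.shape!r}")
        if self.shape == "cylinder":
            if not (self.radius and self.radius > 0 and self.height and self.height > 0):
                raise ConfigurationError("cylinder region needs radius > 0 and height > 0")
        else:
            if self.half_widths is None or any(h <= 0 for h in self.half_widths):
                raise ConfigurationError("box region needs strictly positive half_widths")

    def contains(self, points: np.ndarray, coords: str) -> np.ndarray:
        """Boolean mask of points inside the region.

        ``coords`` is ``"rz"`` (columns r, z) or ``"xyz"``.
        """
        pts = np.asarray(points, dtype=float)
        cx, cy, cz = self.center
        if coords == "rz":
            r = pts[:, 0]
            z = pts[:, 1]
            if abs(cx) > 0 or abs(cy) > 0:
                raise ConfigurationError("rz maps require an on-axis region center")
            if self.shape == "cylinder":
                return (r <= self.radius + 1e-12) & (np.abs(z - cz) <= self.height / 2 + 1e-12)
            hw = self.half_widths
            return (r <= hw[0] + 1e-12) & (np.abs(z - cz) <= hw[2] + 1e-12)
        if coords == "xyz":
            d = pts - np.array([cx, cy, cz])
            if self.shape == "cylinder":
                return (np.hypot(d[:, 0], d[:, 1]) <= self.radius + 1e-12) & (
                    np.abs(d[:, 2]) <= self.height / 2 + 1e-12
                )
            hw = np.asarray(self.half_widths)
            return np.all(np.abs(d) <= hw + 1e-12, axis=1)
        raise ConfigurationError(f"unknown coordinate kind {coords!r}")


@dataclass
class FieldMap:
    """Sampled magnetic field.

    ``points``: (N, 2) array of (r, z) for axisymmetric maps (``coords="rz"``)
    or (N, 3) of (x, y, z) (``coords="xyz"``), in meters.
    ``B``: (N, 2) of (B_r, B_z) or (N, 3) of (B_x, B_y, B_z), in tesla.
    ``inside_winding``: samples lying inside a winding volume; these are
    excluded from region statistics (near-filament values are meaningless
    under the filament discretization).
    """

    points: np.ndarray
    B: np.ndarray
    coords: str = "rz"
    inside_winding: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.points.shape[0] != self.B.shape[0]:
            raise ConfigurationError("one B vector per sample point is required")
        if self.inside_winding is None:
            self.inside_winding = np.zeros(len(self.points), dtype=bool)
        else:
            self.inside_winding = np.asarray(self.inside_winding, dtype=bool)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def magnitude_mT(self) -> np.ndarray:
        """|B| per sample, in millitesla."""
        return np.linalg.norm(self.B, axis=1) * 1e3

    def scaled(self, factor: float) -> "FieldMap":
        """Map with every field vector scaled by ``factor`` (linearity)."""
        return replace(self, B=self.B * factor)


@dataclass(frozen=True)
class HomogeneityReport:
    """Extrema and homogeneity of |B| over a region, in mT and percent."""

    B_max: float
    B_min: float
    B_mean: float
    homogeneity: float
    n_points: int
    n_excluded: int = 0
    region: str = "region"


def homogeneity(fmap: FieldMap, region: RegionSpec) -> HomogeneityReport:
    """Evaluate the homogeneity metric of ``fmap`` over ``region``.

    Samples inside winding volumes are excluded (counted in ``n_excluded``).
    Raises :class:`EmptyRegionError` if fewer than 2 usable samples remain.
    """
    inside = region.contains(fmap.points, fmap.coords)
    excluded = int(np.sum(inside & fmap.inside_winding))
    usable = inside & ~fmap.inside_winding
    mags = fmap.magnitude_mT[usable]
    if mags.size < 2:
        raise EmptyRegionError(
            f"region {region.name!r} contains {mags.size} usable field samples (>= 2 required)"
        )
    b_max = float(mags.max())
    b_min = float(mags.min())
    b_mean = float(mags.mean())
    return HomogeneityReport(
        B_max=b_max,
        B_min=b_min,
        B_mean=b_mean,
        homogeneity=(b_max - b_min) / b_mean * 100.0,
        n_points=int(mags.size),
        n_excluded=excluded,
        region=region.name,
    )


def grid_rz(r_max: float, z_min: float, z_max: float, spacing: float = 1e-3) -> np.ndarray:
    """Rectangular (r, z) sample grid at the given spacing, r from 0.

    Points are ordered lexicographically (r-major, then z).
    """
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be > 0")
    r = np.arange(0.0, r_max + spacing / 2, spacing)
    z = np.arange(z_min, z_max + spacing / 2, spacing)
    rr, zz = np.meshgrid(r, z, indexing="ij")
    return np.column_stack([rr.ravel(), zz.ravel()])


_HEADERS = {
    "rz": ["r_m", "z_m", "Br_T", "Bz_T", "Bmag_mT", "inside_winding"],
    "xyz": ["x_m", "y_m", "z_m", "Bx_T", "By_T", "Bz_T", "Bmag_mT", "inside_winding"],
}


def export_field_map(fmap: FieldMap, path) -> None:
    """Write the map as delimited text (one row per sample, header line).

    Values are written with 17 significant digits so a round trip through
    :func:`read_field_map` is bit-exact.
    """
    if len(fmap) == 0:
        raise ConfigurationError("refusing to export an empty field map")
    ncoord = fmap.points.shape[1]
    order = np.lexsort(tuple(fmap.points[:, i] for i in reversed(range(ncoord))))
    data = np.column_stack(
        [
            fmap.points[order],
            fmap.B[order],
            fmap.magnitude_mT[order],
            fmap.inside_winding[order].astype(float),
        ]
    )
    header = ",".join(_HEADERS[fmap.coords])
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")


def read_field_map(path) -> FieldMap:
    """Read a map written by :func:`export_field_map`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    coords = "rz" if header == _HEADERS["rz"] else "xyz"
    data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
    ncoord = 2 if coords == "rz" else 3
    return FieldMap(
        points=data[:, :ncoord],
        B=data[:, ncoord : 2 * ncoord],
        coords=coords,
        inside_winding=data[:, -1] > 0.5,
    )
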