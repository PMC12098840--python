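"""Published solenoid apparatus geometries and their evaluation regions.

Three fully axisymmetric apparatuses from the platform this toolkit models:

* ``microscopy_coil`` — single coil for fluorescence microscopy: 3.5 cm
  inner diameter, 13.5 cm outer diameter, 4 cm tall, 2000 turns of 18 AWG,
  driven at 2.2 A.  Evaluated over the central 2 cm x 2 cm sagittal region.
* ``arena_10cm_array`` — four coils (11 cm bore, 21 cm outer diameter, 4 cm
  tall, 500 turns of 12 AWG each) stacked with 1, 2, 1 cm gaps, 6 A,
  surrounding a 10 cm behavioral arena.  Evaluated over central cylinders of
  10 cm diameter and 5 / 10 / 15 cm height.
* ``arena_20cm_array`` — six coils (21 cm bore, 5 cm tall, 4 cm radial
  build, 500 turns of 12 AWG each) with 1, 2, 1, 2, 1 cm gaps, 7 A, for a
  20 cm arena.  Evaluated over central cylinders of 20 cm diameter and
  5 / 10 / 15 / 20 cm height.

Regions are centered on the array's geometric mid-plane.  A fourth,
non-axisymmetric design (``multiwell_rect_coil``) drives multi-well culture
dishes.
"""

from __future__ import annotations

from .coils import CoilArraySpec, CoilSpec
from .fieldmap import RegionSpec
from .rect import RectCoilSpec

__all__ = [
    "microscopy_coil",
    "arena_10cm_array",
    "arena_20cm_array",
    "multiwell_rect_coil",
    "APPARATUS",
]


def microscopy_coil(current: float = 2.2) -> tuple[CoilArraySpec, dict]:
    coil = CoilSpec(
        inner_radius=0.0175,
        radial_build=0.05,
        axial_length=0.04,
        turns=2000,
        current=current,
        axial_center=0.0,
        wire_gauge=18,
    )
    regions = {
        "center_2x2cm": RegionSpec(
            shape="box",
            half_widths=(0.01, 0.01, 0.01),
            name="center_2x2cm",
        )
    }
    return CoilArraySpec(coils=[coil]), regions


def _stack(coil_length: float, gaps: list[float], make_coil) -> list[CoilSpec]:
    n = len(gaps) + 1
    span = n * coil_length + sum(gaps)
    coils = []
    z = -span / 2.0
    for i in range(n):
        coils.append(make_coil(z + coil_length / 2.0))
        z += coil_length + (gaps[i] if i < len(gaps) else 0.0)
    return coils


def arena_10cm_array(current: float = 6.0) -> tuple[CoilArraySpec, dict]:
    def make(center: float) -> CoilSpec:
        return CoilSpec(
            inner_radius=0.055,
            radial_build=0.05,
            axial_length=0.04,
            turns=500,
            current=current,
            axial_center=center,
            wire_gauge=12,
        )

    coils = _stack(0.04, [0.01, 0.02, 0.01], make)
    regions = {
        f"cylinder_h{h_cm}cm": RegionSpec(
            shape="cylinder", radius=0.05, height=h_cm / 100.0, name=f"cylinder_h{h_cm}cm"
        )
        for h_cm in (5, 10, 15)
    }
    return CoilArraySpec(coils=coils), regions


def arena_20cm_array(current: float = 7.0) -> tuple[CoilArraySpec, dict]:
    def make(center: float) -> CoilSpec:
        return CoilSpec(
            inner_radius=0.105,
            radial_build=0.04,
            axial_length=0.05,
            turns=500,
            current=current,
            axial_center=center,
            wire_gauge=12,
        )

    coils = _stack(0.05, [0.01, 0.02, 0.01, 0.02, 0.01], make)
    regions = {
        f"cylinder_h{h_cm}cm": RegionSpec(
            shape="cylinder", radius=0.10, height=h_cm / 100.0, name=f"cylinder_h{h_cm}cm"
        )
        for h_cm in (5, 10, 15, 20)
    }
    return CoilArraySpec(coils=coils), regions


def multiwell_rect_coil(current: float = 3.2) -> RectCoilSpec:
    """Rectangular cuboid coil for 24-well culture dishes (3000 turns total)."""
    return RectCoilSpec(
        inner_width=0.095,
        inner_height=0.035,
        outer_width=0.125,
        outer_height=0.075,
        length=0.20,
        turns=3000,
        current=current,
    )


#: named apparatus factories for the CLI and acceptance tooling
APPARATUS = {
    "microscopy_3p5cm": microscopy_coil,
    "arena_10cm": arena_10cm_array,
    "arena_20cm": arena_20cm_array,
}


def evaluate_apparatus(
    name: str, spacing: float = 1e-3, n_r: int = 20, n_z: int = 20
) -> dict:
    """Sample |B| over an apparatus' regions and report homogeneity.

    The grid covers the largest configured region at ``spacing`` (1 mm by
    default) in the axisymmetric (r, z) half-plane; every region report is
    computed from that one map.  Returns {region name: HomogeneityReport}.
    """
    from .coils import array_field
    from .fieldmap import grid_rz, homogeneity

    array, regions = APPARATUS[name]()
    r_max = max(
        (reg.radius if reg.shape == "cylinder" else reg.half_widths[0])
        for reg in regions.values()
    )
    z_half = max(
        (reg.height / 2 if reg.shape == "cylinder" else reg.half_widths[2])
        for reg in regions.values()
    )
    fmap = array_field(array, grid_rz(r_max, -z_half, z_half, spacing), n_r=n_r, n_z=n_z)
    return {name_: homogeneity(fmap, reg) for name_, reg in regions.items()}
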