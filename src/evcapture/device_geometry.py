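"""Micropillar-bed and device geometry, plus the derived design metrics.

An affinity-capture bed is a shallow rectangular channel populated with a
dense array of micropillars (circular or diamond cross-section).  Antibodies
are immobilized on every internal surface, so the quantities that matter for
assay design are the total internal surface area, the monolayer particle
load that area can hold, and the antibody coverage achieved on it.

All lengths are stored internally in SI meters; constructors accept the
natural bench units (mm / µm) via the helper classmethods and the config
loader in :mod:`evcapture.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence, Tuple

__all__ = [
    "BedGeometry",
    "DeviceGeometry",
    "InvalidGeometryError",
    "HEX_PACKING",
    "internal_surface_area",
    "ev_load_capacity",
    "antibody_coverage",
    "open_cross_section",
]

#: Densest planar packing fraction of equal circles, pi / (2 sqrt(3)).
HEX_PACKING: float = math.pi / (2.0 * math.sqrt(3.0))


class InvalidGeometryError(ValueError):
    """Raised when a bed/device description is geometrically impossible."""


@dataclass(frozen=True)
class BedGeometry:
    """One micropillar bed.

    Parameters
    ----------
    length, width : float
        Flow-path length and bed width, meters.
    depth : float
        Channel depth, meters.
    pillar_shape : {"circular", "diamond"}
        Pillar cross-section.  ``pillar_size`` is the diameter for circular
        pillars and the side length for diamond (square rotated 45°) pillars.
    pillar_size, pillar_spacing : float
        Pillar size and inter-pillar gap, meters.
    n_pillars : int
        Total pillar count in the bed.
    """

    length: float
    width: float
    depth: float
    pillar_shape: Literal["circular", "diamond"]
    pillar_size: float
    pillar_spacing: float
    n_pillars: int

    def __post_init__(self) -> None:
        for name in ("length", "width", "depth", "pillar_size", "pillar_spacing"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.pillar_shape not in ("circular", "diamond"):
            raise InvalidGeometryError(
                f"unknown pillar_shape {self.pillar_shape!r}"
            )
        if self.n_pillars < 0:
            raise InvalidGeometryError("n_pillars must be >= 0")
        if self.pillar_footprint_total >= self.length * self.width:
            raise InvalidGeometryError(
                "total pillar footprint exceeds the bed floor area"
            )

    # -- per-pillar primitives -------------------------------------------
    @property
    def pillar_perimeter(self) -> float:
        """Perimeter of one pillar cross-section, m."""
        if self.pillar_shape == "circular":
            return math.pi * self.pillar_size
        return 4.0 * self.pillar_size  # diamond: square of side pillar_size

    @property
    def pillar_footprint(self) -> float:
        """Cross-sectional area of one pillar, m²."""
        if self.pillar_shape == "circular":
            return math.pi * (self.pillar_size / 2.0) ** 2
        return self.pillar_size**2

    @property
    def pillar_footprint_total(self) -> float:
        return self.n_pillars * self.pillar_footprint

    @property
    def floor_area(self) -> float:
        """Open floor area (bed footprint minus pillar footprints), m²."""
        return self.length * self.width - self.pillar_footprint_total

    @property
    def surface_area(self) -> float:
        """Internal capture surface, m²: pillar walls + floor + ceiling.

        Side walls and inlet/outlet manifolds are excluded; for a dense
        pillar array they are a negligible fraction of the total.
        """
        pillar_lateral = self.pillar_perimeter * self.depth * self.n_pillars
        return pillar_lateral + 2.0 * self.floor_area

    @property
    def open_width_fraction(self) -> float:
        """Fraction of the bed width that is open at a pillar-row constriction.

        An unpillared bed has no constriction, so the fraction is 1.
        """
        if self.n_pillars == 0:
            return 1.0
        return self.pillar_spacing / (self.pillar_spacing + self.pillar_size)

    @property
    def open_cross_section(self) -> float:
        """Open flow cross-section at a pillar row, m²."""
        return self.width * self.depth * self.open_width_fraction

    @property
    def internal_volume(self) -> float:
        """Fluid volume of the bed, m³ (bed volume minus pillar volume)."""
        return self.floor_area * self.depth


@dataclass(frozen=True)
class DeviceGeometry:
    """A capture device: one or more beds in series or in parallel.

    Serial beds share the full volumetric flow in sequence; parallel beds
    split it evenly, which requires all beds to be identical.
    """

    beds: Tuple[BedGeometry, ...]
    arrangement: Literal["serial", "parallel"]
    name: str = "device"

    def __init__(
        self,
        beds: Sequence[BedGeometry],
        arrangement: str,
        name: str = "device",
    ) -> None:
        object.__setattr__(self, "beds", tuple(beds))
        object.__setattr__(self, "arrangement", arrangement)
        object.__setattr__(self, "name", name)
        if not self.beds:
            raise InvalidGeometryError("device needs at least one bed")
        if arrangement not in ("serial", "parallel"):
            raise InvalidGeometryError(f"unknown arrangement {arrangement!r}")
        if arrangement == "parallel" and len(set(self.beds)) > 1:
            raise InvalidGeometryError(
                "parallel arrangement requires identical beds (uniform flow split)"
            )

    @property
    def n_beds(self) -> int:
        return len(self.beds)

    @property
    def surface_area(self) -> float:
        return sum(b.surface_area for b in self.beds)

    @property
    def internal_volume(self) -> float:
        return sum(b.internal_volume for b in self.beds)

    @property
    def total_flow_cross_section(self) -> float:
        """Raw (not pillar-corrected) cross-section carrying flow, m².

        Parallel beds add; serial beds all carry the same flow so the
        single-bed value applies.
        """
        if self.arrangement == "parallel":
            return sum(b.width * b.depth for b in self.beds)
        return self.beds[0].width * self.beds[0].depth


def internal_surface_area(device: DeviceGeometry) -> float:
    """Total internal capture surface area of a device, cm².

    Sum over beds of pillar lateral area (perimeter × depth × count) plus
    floor and ceiling (2 × (bed footprint − pillar footprint)).
    """
    return device.surface_area * 1e4  # m² -> cm²


def ev_load_capacity(
    area_cm2: float, ev_diameter: float, packing: float = HEX_PACKING
) -> float:
    """Monolayer particle load a surface can hold.

    Parameters
    ----------
    area_cm2 : float
        Capture surface area, cm².
    ev_diameter : float
        Particle diameter, meters.
    packing : float
        Planar packing fraction in (0, 1]; defaults to hexagonal close
        packing pi/(2 sqrt 3) ≈ 0.9069.

    Returns
    -------
    float
        Maximum particle count, ``packing × area / (π (d/2)²)``.
    """
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    if ev_diameter <= 0:
        raise ValueError("non-physical particle diameter")
    if not 0 < packing <= 1:
        raise ValueError("packing fraction must be in (0, 1]")
    area_m2 = area_cm2 * 1e-4
    return packing * area_m2 / (math.pi * (ev_diameter / 2.0) ** 2)


def antibody_coverage(
    mass_ug: float, molar_mass_kda: float, area_cm2: float
) -> Tuple[float, float]:
    """Convert an immobilized antibody mass into molar amount and coverage.

    Returns ``(amount_pmol, density_pmol_per_cm2)``.  A 150 kDa IgG is the
    usual molar mass for monoclonal capture antibodies.
    """
    if mass_ug < 0:
        raise ValueError("antibody mass must be >= 0")
    if molar_mass_kda <= 0 or area_cm2 <= 0:
        raise ValueError("molar mass and area must be positive")
    # µg / kDa = 1e-6 g / (1e3 g/mol) = 1e-9 mol = nmol; ×1e3 -> pmol
    amount_pmol = mass_ug / molar_mass_kda * 1e3
    return amount_pmol, amount_pmol / area_cm2


def open_cross_section(device: DeviceGeometry) -> float:
    """Open flow cross-section of the device at a pillar-row constriction, m².

    For parallel devices the beds add; for serial devices every bed carries
    the full flow so the single (first) bed value is returned.  The open
    width fraction is ``spacing / (spacing + pillar_size)`` — the velocity
    between pillars is the capture-relevant velocity.
    """
    if device.arrangement == "parallel":
        return sum(b.open_cross_section for b in device.beds)
    return device.beds[0].open_cross_section
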