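"""Perforated-MEA hole layouts, open-area ratios and homogenized conductance.

A perforated MEA trades electrode density against oxygen delivery: diffusion
holes opened between the microelectrodes let the perfusate reach the tissue,
and the fraction of surface they occupy (the open-area ratio, OAR) sets how
much of the slab behaves as a diffusive window.  Rather than meshing tens of
thousands of 10-100 um holes in a mm-scale chamber, the array is homogenized
into an effective conductance layer: flux across the MEA = conductance * dP,
with conductance = OAR * dk_fluid / thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import InvalidParameterError

__all__ = [
    "HoleRegion",
    "MEADesign",
    "region_oar",
    "pitch_for_oar",
    "effective_oar",
    "membrane_conductance",
    "default_mea_design",
    "hole_layout_table",
]


class GeometryError(ValueError):
    """Hole geometry is physically impossible (e.g. overlapping holes)."""


class InvalidDesignError(ValueError):
    """An MEA design violates its structural invariants."""


@dataclass(frozen=True)
class HoleRegion:
    """One annular region of the MEA with a uniform hole size and OAR.

    The fabricated arrays use three regions: the electrode-crowded center
    (10 um holes, 10% OAR) and the middle/outer regions (50 and 100 um holes,
    20% OAR each).
    """

    name: str
    hole_diameter_um: float
    oar: float
    area_cm2: float

    def __post_init__(self) -> None:
        if not self.hole_diameter_um > 0:
            raise InvalidDesignError("hole_diameter must be positive")
        if not (0 < self.oar <= 1):
            raise InvalidDesignError("oar must lie in (0, 1]")
        if not self.area_cm2 > 0:
            raise InvalidDesignError("region area must be positive")


@dataclass(frozen=True)
class MEADesign:
    """A perforated MEA: ordered hole regions plus electrode metrology."""

    regions: tuple[HoleRegion, ...]
    thickness_um: float = 20.0
    electrode_diameter_um: float = 11.5
    electrode_pitch_um: float = 30.0

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise InvalidDesignError("thickness must be positive")
        object.__setattr__(self, "regions", tuple(self.regions))

    @property
    def thickness_cm(self) -> float:
        return self.thickness_um * 1e-4

    @property
    def total_area_cm2(self) -> float:
        return sum(r.area_cm2 for r in self.regions)


def region_oar(hole_diameter_um: float, pitch_um: float, lattice: str = "square") -> float:
    """OAR of a periodic hole lattice with hole diameter ``d`` and pitch ``p``.

    square lattice: pi d^2 / (4 p^2); hexagonal: pi d^2 / (2 sqrt(3) p^2).
    """
    if not hole_diameter_um > 0 or not pitch_um > 0:
        raise InvalidParameterError("diameter and pitch must be positive")
    if hole_diameter_um >= pitch_um:
        raise GeometryError("holes overlap: diameter must be smaller than pitch")
    d2p2 = (hole_diameter_um / pitch_um) ** 2
    if lattice == "square":
        return math.pi * d2p2 / 4.0
    if lattice == "hex":
        return math.pi * d2p2 / (2.0 * math.sqrt(3.0))
    raise InvalidParameterError(f"unknown lattice {lattice!r}")


def pitch_for_oar(hole_diameter_um: float, oar: float, lattice: str = "square") -> float:
    """Invert :func:`region_oar`: the pitch that realizes a target OAR."""
    if not (0 < oar < 1):
        raise InvalidParameterError("target oar must lie in (0, 1)")
    if lattice == "square":
        return hole_diameter_um * math.sqrt(math.pi / (4.0 * oar))
    if lattice == "hex":
        return hole_diameter_um * math.sqrt(math.pi / (2.0 * math.sqrt(3.0) * oar))
    raise InvalidParameterError(f"unknown lattice {lattice!r}")


def effective_oar(design: MEADesign) -> float:
    """Area-weighted mean OAR over the design's regions.

    For the default three-region layout this is the 18.9% whole-surface
    average quoted for the fabricated arrays.
    """
    if not design.regions:
        raise InvalidDesignError("design has no hole regions")
    total = design.total_area_cm2
    return sum(r.oar * r.area_cm2 for r in design.regions) / total


def membrane_conductance(oar: float, dk_fluid: float, thickness_cm: float) -> float:
    """Per-area diffusive conductance of a homogenized perforated slab.

    Units: ml O2 cm^-2 min^-1 mmHg^-1 (per 100 g when ``dk_fluid`` carries the
    per-100 g normalization).  Flux across the MEA = conductance * dP, the
    homogenized form of the thin-slab gradient approximation dP/dz ~ dP / t.
    ``oar = 0`` (solid plate) is allowed and blocks diffusion entirely.
    """
    if not thickness_cm > 0:
        raise InvalidParameterError("thickness must be strictly positive")
    if not dk_fluid > 0:
        raise InvalidParameterError("dk_fluid must be strictly positive")
    if oar < 0 or oar > 1:
        raise InvalidParameterError("oar must lie in [0, 1]")
    return oar * dk_fluid / thickness_cm


# Concentric area fractions of the 1 mm tissue window for center/middle/outer
# regions.  The center fraction is fixed by requiring the area-weighted OAR of
# the printed 10/20/20% regions to equal the printed 18.9% whole-surface
# average: 0.10 f + 0.20 (1 - f) = 0.189  =>  f = 0.11.
_DEFAULT_AREA_FRACTIONS = (0.11, 0.25, 0.64)


def default_mea_design(
    window_diameter_mm: float = 1.0, thickness_um: float = 20.0
) -> MEADesign:
    """The fabricated three-region perforated MEA over a 1 mm window."""
    r_cm = window_diameter_mm * 0.1 / 2.0
    total = math.pi * r_cm * r_cm
    f_c, f_m, f_o = _DEFAULT_AREA_FRACTIONS
    regions = (
        HoleRegion("center", 10.0, 0.10, f_c * total),
        HoleRegion("middle", 50.0, 0.20, f_m * total),
        HoleRegion("outer", 100.0, 0.20, f_o * total),
    )
    return MEADesign(regions=regions, thickness_um=thickness_um)


def uniform_mea_design(
    oar: float,
    hole_diameter_um: float = 50.0,
    window_diameter_mm: float = 1.0,
    thickness_um: float = 20.0,
) -> MEADesign:
    """Single-region design with one OAR everywhere (used for OAR sweeps)."""
    r_cm = window_diameter_mm * 0.1 / 2.0
    total = math.pi * r_cm * r_cm
    return MEADesign(
        regions=(HoleRegion("uniform", hole_diameter_um, oar, total),),
        thickness_um=thickness_um,
    )


def hole_layout_table(design: MEADesign, lattice: str = "square") -> pd.DataFrame:
    """Explicit hole centers/diameters for plotting or export.

    Regions are laid out as concentric annuli; hole centers are placed on the
    region's lattice (pitch chosen from the region OAR) and kept if they fall
    inside the annulus.  Columns: region, x_um, y_um, diameter_um.
    """
    total = design.total_area_cm2
    r_outer_cm = math.sqrt(total / math.pi)
    rows = []
    r_in = 0.0
    cum = 0.0
    for region in design.regions:
        cum += region.area_cm2
        r_out = r_outer_cm * math.sqrt(cum / total)
        pitch = pitch_for_oar(region.hole_diameter_um, region.oar, lattice)
        r_in_um, r_out_um = r_in * 1e4, r_out * 1e4
        n = int(r_out_um / pitch) + 1
        coords = np.arange(-n, n + 1) * pitch
        xx, yy = np.meshgrid(coords, coords)
        rr = np.hypot(xx, yy)
        keep = (rr >= r_in_um) & (rr < r_out_um)
        for x, y in zip(xx[keep], yy[keep]):
            rows.append((region.name, float(x), float(y), region.hole_diameter_um))
        r_in = r_out
    return pd.DataFrame(rows, columns=["region", "x_um", "y_um", "diameter_um"])
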