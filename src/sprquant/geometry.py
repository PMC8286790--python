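"""Particle geometry and monolayer packing model.

Rod-shaped bacteria are reduced to an equivalent sphere of the same volume.
A hexagonally packed monolayer of such spheres is then collapsed into an
even, homogeneous slab whose thickness is

    diameter x area_packing_fraction x volume_fill_factor

which is the adlayer thickness fed to the optical model.  The per-particle
sensor footprint is the projected circle of the equivalent sphere.

Units: lengths in nm unless a name says otherwise; volumes cross the API
boundary in um^3 (1 um^3 = 1e9 nm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from sprquant.errors import ValidationError

ShapeModel = Literal["cylinder", "spherocylinder", "ellipsoid"]

#: Canonical BCG cell volume (um^3) used as the default particle fixture.
BCG_VOLUME_UM3 = 0.3887
#: Refractive index assumed for the bacterial particle.
BCG_REFRACTIVE_INDEX = 1.35
#: Area fraction of the sensor plane reachable by packed particles.
DEFAULT_AREA_PACKING_FRACTION = 0.74
#: Sphere-to-slab volume fill factor (sphere volume / circumscribing cube).
DEFAULT_VOLUME_FILL_FACTOR = 0.524


@dataclass(frozen=True)
class RodDimensions:
    """End-to-end length and width (diameter) of a rod-shaped cell, in um."""

    length_um: float
    width_um: float

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise ValidationError(f"rod width must be > 0, got {self.width_um}")
        if self.length_um < self.width_um:
            raise ValidationError(
                f"rod length ({self.length_um}) must be >= width ({self.width_um})"
            )


@dataclass(frozen=True)
class PackingParameters:
    """Monolayer packing constants.

    ``area_packing_fraction`` is the fraction of the sensor plane that a
    packed layer of particles can cover (default 0.74).  Note this equals
    the 3-D close-packing fraction; 2-D hexagonal disc packing would be
    ~0.907 — the 0.74 convention is kept deliberately to match the
    established estimation chain.  ``volume_fill_factor`` converts a sphere
    into the even slab of equal volume over its bounding square
    (pi/6 ~ 0.524).
    """

    area_packing_fraction: float = DEFAULT_AREA_PACKING_FRACTION
    volume_fill_factor: float = DEFAULT_VOLUME_FILL_FACTOR

    def __post_init__(self) -> None:
        for name in ("area_packing_fraction", "volume_fill_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")


def rod_volume(dims: RodDimensions, shape_model: ShapeModel = "spherocylinder") -> float:
    """Volume of a rod-shaped cell in um^3 under a chosen shape model.

    Parameters
    ----------
    dims : RodDimensions
        Length and width in um.
    shape_model : {"cylinder", "spherocylinder", "ellipsoid"}
        cylinder: ``pi (w/2)^2 L``; spherocylinder: cylinder of length
        ``L - w`` with hemispherical caps; ellipsoid: prolate spheroid
        ``(pi/6) L w^2``.
    """
    L, w = dims.length_um, dims.width_um
    r = w / 2.0
    if shape_model == "cylinder":
        return math.pi * r * r * L
    if shape_model == "spherocylinder":
        return math.pi * r * r * (L - w) + (4.0 / 3.0) * math.pi * r**3
    if shape_model == "ellipsoid":
        return (math.pi / 6.0) * L * w * w
    raise ValidationError(f"unknown shape_model {shape_model!r}")


def equivalent_sphere_diameter(volume_um3: float) -> float:
    """Diameter (nm) of the sphere with the given volume (um^3)."""
    if not volume_um3 > 0:
        raise ValidationError(f"volume must be > 0, got {volume_um3}")
    return 1000.0 * (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def sphere_volume(diameter_nm: float) -> float:
    """Volume (um^3) of a sphere of the given diameter (nm); inverse of
    :func:`equivalent_sphere_diameter`."""
    if not diameter_nm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_nm}")
    return (math.pi / 6.0) * (diameter_nm / 1000.0) ** 3


def effective_layer_thickness(diameter_nm: float, packing: PackingParameters) -> float:
    """Even homogeneous slab thickness (nm) of a packed full monolayer.

    The particle diameter is scaled first by the area packing fraction and
    then by the sphere-to-slab fill factor.
    """
    if not diameter_nm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_nm}")
    return diameter_nm * packing.area_packing_fraction * packing.volume_fill_factor


def footprint_area(diameter_nm: float) -> float:
    """Projected circular area (nm^2) one particle occupies on the sensor."""
    if not diameter_nm > 0:
        raise ValidationError(f"diameter must be > 0, got {diameter_nm}")
    return math.pi * (diameter_nm / 2.0) ** 2


@dataclass(frozen=True)
class ParticleModel:
    """Equivalent-sphere particle with optical and packing attributes.

    Construct either from a direct volume (:meth:`from_volume`) or from rod
    dimensions plus a shape model (:meth:`from_rod`).
    """

    volume_um3: float
    refractive_index: float = BCG_REFRACTIVE_INDEX
    packing: PackingParameters = field(default_factory=PackingParameters)

    def __post_init__(self) -> None:
        if not self.volume_um3 > 0:
            raise ValidationError(f"particle volume must be > 0, got {self.volume_um3}")
        if not self.refractive_index > 0:
            raise ValidationError(
                f"refractive index must be > 0, got {self.refractive_index}"
            )

    @classmethod
    def from_volume(cls, volume_um3: float, **kwargs) -> "ParticleModel":
        return cls(volume_um3=volume_um3, **kwargs)

    @classmethod
    def from_rod(
        cls,
        dims: RodDimensions,
        shape_model: ShapeModel = "spherocylinder",
        **kwargs,
    ) -> "ParticleModel":
        return cls(volume_um3=rod_volume(dims, shape_model), **kwargs)

    @classmethod
    def bcg_default(cls) -> "ParticleModel":
        """The canonical BCG fixture: V = 0.3887 um^3, n = 1.35, packing
        (0.74, 0.524)."""
        return cls(volume_um3=BCG_VOLUME_UM3)

    @property
    def equivalent_diameter_nm(self) -> float:
        return equivalent_sphere_diameter(self.volume_um3)

    @property
    def effective_layer_thickness_nm(self) -> float:
        return effective_layer_thickness(self.equivalent_diameter_nm, self.packing)

    @property
    def footprint_area_nm2(self) -> float:
        return footprint_area(self.equivalent_diameter_nm)
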