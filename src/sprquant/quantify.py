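"""Steady-state angular responses to surface coverage, particle counts,
adsorbed mass and molecules per particle.

The estimation chain:

1. coverage = immobilization response / modeled full-monolayer response
2. particles = coverage x detection-spot area / per-particle footprint
3. mass/area = k x analyte binding response (k in ng/cm^2 per degree)
4. total mass = mass/area x spot area
5. molecules = mass / molecular weight x Avogadro
6. molecules per particle = molecules / particles

All steps are exposed individually and composed by :func:`run_chain`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from sprquant.errors import CoverageModelError, ValidationError

#: Avogadro constant, exact 2019 SI value (1/mol).
AVOGADRO = 6.02214076e23
#: nm^2 per cm^2.
NM2_PER_CM2 = 1.0e14
#: Default mass conversion, ng/cm^2 per degree of SPR response.
DEFAULT_MASS_CONVERSION = 600.0
#: Default laser detection-spot diameter, mm.
DEFAULT_SPOT_DIAMETER_MM = 1.0

Anchor = Literal["polyK", "CPP", "none"]


@dataclass(frozen=True)
class DetectionSpot:
    """Circular detection area set by the instrument laser diameter (mm)."""

    diameter_mm: float = DEFAULT_SPOT_DIAMETER_MM

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValidationError(f"spot diameter must be > 0, got {self.diameter_mm}")

    @property
    def area_nm2(self) -> float:
        r_nm = self.diameter_mm * 1e6 / 2.0
        return math.pi * r_nm * r_nm

    @property
    def area_cm2(self) -> float:
        return self.area_nm2 / NM2_PER_CM2


@dataclass(frozen=True)
class PeptideSpec:
    """Analyte peptide: display name, molecular weight (g/mol), anchor type."""

    name: str
    molecular_weight: float
    anchor: Anchor = "none"

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValidationError(
                f"peptide {self.name!r}: molecular weight must be > 0"
            )


@dataclass(frozen=True)
class MassConversionConstant:
    """Angular-response-to-surface-mass conversion, ng/cm^2 per degree."""

    k: float = DEFAULT_MASS_CONVERSION

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError(f"mass conversion constant must be > 0, got {self.k}")


@dataclass(frozen=True)
class MeasurementRecord:
    """Steady-state responses for one peptide measurement.

    ``binding_response`` is the reference-corrected analyte plateau
    (active minus uncoated channel), in degrees.
    """

    peptide: PeptideSpec
    immobilization_response: float
    binding_response: float
    analyte_concentration_um: Optional[float] = 100.0
    reference_corrected: bool = True

    def __post_init__(self) -> None:
        if self.immobilization_response < 0:
            raise ValidationError("immobilization response must be >= 0")
        if self.binding_response < 0:
            raise ValidationError("binding response must be >= 0")


@dataclass(frozen=True)
class QuantificationResult:
    """Full output of the estimation chain for one peptide."""

    peptide: str
    coverage_fraction: float
    particle_count: float
    mass_per_area_ng_cm2: float
    total_mass_ng: float
    molecule_count: float
    molecules_per_particle: float

    @property
    def particle_count_rounded(self) -> int:
        return _round_half_away(self.particle_count)

    @property
    def molecule_count_rounded(self) -> int:
        return _round_half_away(self.molecule_count)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def coverage_fraction(measured_deg: float, max_monolayer_deg: float) -> float:
    """Fraction of the detection area covered by particles.

    Ratio of the measured immobilization response to the modeled
    full-monolayer maximum.  Values above 1 violate the monolayer model and
    raise :class:`CoverageModelError`.
    """
    if not max_monolayer_deg > 0:
        raise ValidationError(
            f"max monolayer response must be > 0, got {max_monolayer_deg}"
        )
    if measured_deg < 0:
        raise ValidationError(f"measured response must be >= 0, got {measured_deg}")
    cov = measured_deg / max_monolayer_deg
    if cov > 1.0:
        raise CoverageModelError(
            f"measured response {measured_deg} deg exceeds modeled monolayer "
            f"maximum {max_monolayer_deg} deg (coverage {cov:.3f} > 1)"
        )
    return cov


def particle_count(coverage: float, spot: DetectionSpot, footprint_nm2: float) -> float:
    """Number of particles in the detection spot (real-valued)."""
    if not footprint_nm2 > 0:
        raise ValidationError(f"footprint must be > 0, got {footprint_nm2}")
    if coverage < 0:
        raise ValidationError(f"coverage must be >= 0, got {coverage}")
    return coverage * spot.area_nm2 / footprint_nm2


def mass_per_area(binding_response_deg: float, k: MassConversionConstant) -> float:
    """Adsorbed analyte surface mass density, ng/cm^2."""
    if binding_response_deg < 0:
        raise ValidationError("binding response must be >= 0")
    return k.k * binding_response_deg


def total_mass(mass_per_area_ng_cm2: float, spot: DetectionSpot) -> float:
    """Absolute adsorbed mass (ng) over the detection spot."""
    if mass_per_area_ng_cm2 < 0:
        raise ValidationError("mass per area must be >= 0")
    return mass_per_area_ng_cm2 * spot.area_cm2


def molecule_count(mass_ng: float, peptide: PeptideSpec) -> float:
    """Number of molecules in the given mass of the peptide."""
    if mass_ng < 0:
        raise ValidationError("mass must be >= 0")
    return mass_ng * 1e-9 / peptide.molecular_weight * AVOGADRO


def molecules_per_particle(molecules: float, particles: float) -> float:
    """Average number of analyte molecules bound per particle."""
    if particles <= 0:
        raise ZeroDivisionError(
            f"particle count must be > 0 to normalize molecules per particle, "
            f"got {particles}"
        )
    return molecules / particles


def run_chain(
    record: MeasurementRecord,
    particle,  # ParticleModel
    stack=None,  # SensorStack; ignored when max_monolayer_deg given
    spot: DetectionSpot = DetectionSpot(),
    k: MassConversionConstant = MassConversionConstant(),
    *,
    max_monolayer_deg: Optional[float] = None,
) -> QuantificationResult:
    """Run the full chain for one measurement record.

    The full-monolayer denominator is taken from ``max_monolayer_deg`` when
    supplied (e.g. precomputed once for a batch), otherwise computed by
    optical modeling of ``stack`` with the particle monolayer adlayer.

    Each output field equals the corresponding single-step operation applied
    to the upstream outputs (exact composition, no re-rounding).
    """
    if max_monolayer_deg is None:
        if stack is None:
            raise ValidationError("run_chain needs either a stack or max_monolayer_deg")
        from sprquant.optics import max_monolayer_response

        max_monolayer_deg = max_monolayer_response(stack, particle)

    try:
        cov = coverage_fraction(record.immobilization_response, max_monolayer_deg)
    except CoverageModelError as exc:
        raise CoverageModelError(f"[coverage] {exc}") from exc
    particles = particle_count(cov, spot, particle.footprint_area_nm2)
    mpa = mass_per_area(record.binding_response, k)
    mass = total_mass(mpa, spot)
    molecules = molecule_count(mass, record.peptide)
    if particles > 0:
        per_particle = molecules_per_particle(molecules, particles)
    else:
        per_particle = float("nan") if molecules > 0 else 0.0
    return QuantificationResult(
        peptide=record.peptide.name,
        coverage_fraction=cov,
        particle_count=particles,
        mass_per_area_ng_cm2=mpa,
        total_mass_ng=mass,
        molecule_count=molecules,
        molecules_per_particle=per_particle,
    )
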