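"""p-polarized multilayer reflectance and SPR dip analysis.

The sensor is a stack of homogeneous, isotropic layers bounded by two
half-spaces: the coupling prism on one side and the running buffer on the
other.  Reflectance is computed with the characteristic (transfer) matrix
method for stratified media.  Conventions:

* time dependence ``exp(-i omega t)``; absorbing media therefore carry a
  positive imaginary refractive-index part;
* the incidence angle is the *internal* angle in the coupling half-space,
  in degrees;
* only p-polarization is implemented (s-polarized light does not excite
  surface plasmons).

The normal wavevector component in layer *j* is
``kz_j = k0 * sqrt(n_j^2 - n_0^2 sin^2 theta)`` with the principal branch
of the complex square root, which keeps evanescent fields decaying under
the chosen time convention.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from sprquant.errors import DipNotFoundError, ValidationError
from sprquant.geometry import ParticleModel

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

#: Default excitation wavelength, nm.
DEFAULT_WAVELENGTH_NM = 670.0
#: Default angular scan window (degrees) and step for dip localization;
#: brackets the dip of the default stack in aqueous ambient.
DEFAULT_ANGLE_MIN = 60.0
DEFAULT_ANGLE_MAX = 85.0
DEFAULT_ANGLE_STEP = 0.005


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous layer: complex refractive index and thickness (nm).

    The two bounding half-spaces carry ``thickness=None``.
    """

    name: str
    refractive_index: complex
    thickness: Optional[float] = None

    def __post_init__(self) -> None:
        n = complex(self.refractive_index)
        if not n.real > 0:
            raise ValidationError(
                f"layer {self.name!r}: real part of refractive index must be > 0"
            )
        if self.thickness is not None and self.thickness < 0:
            raise ValidationError(
                f"layer {self.name!r}: thickness must be >= 0, got {self.thickness}"
            )

    @property
    def is_half_space(self) -> bool:
        return self.thickness is None


@dataclass(frozen=True)
class Adlayer:
    """Homogeneous adsorbed layer inserted at the sensor/ambient interface."""

    refractive_index: float
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValidationError(f"adlayer thickness must be >= 0, got {self.thickness}")
        if not self.refractive_index > 0:
            raise ValidationError("adlayer refractive index must be > 0")


@dataclass(frozen=True)
class SensorStack:
    """Ordered layer stack from coupling half-space to ambient half-space."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 2:
            raise ValidationError("a stack needs at least two half-space layers")
        if not self.layers[0].is_half_space or not self.layers[-1].is_half_space:
            raise ValidationError("first and last layers must be half-spaces")
        for lay in self.layers[1:-1]:
            if lay.is_half_space:
                raise ValidationError(
                    f"interior layer {lay.name!r} must have a finite thickness"
                )
        if not self.wavelength_nm > 0:
            raise ValidationError(f"wavelength must be > 0, got {self.wavelength_nm}")

    @property
    def ambient_index(self) -> complex:
        return complex(self.layers[-1].refractive_index)

    @property
    def coupling_index(self) -> complex:
        return complex(self.layers[0].refractive_index)

    def with_adlayer(self, adlayer: Adlayer) -> "SensorStack":
        """Return a new stack with the adlayer inserted between the outermost
        solid layer and the ambient half-space."""
        extra = OpticalLayer(
            name="adlayer",
            refractive_index=complex(adlayer.refractive_index),
            thickness=adlayer.thickness,
        )
        return replace(self, layers=self.layers[:-1] + (extra, self.layers[-1]))

    @classmethod
    def default(cls) -> "SensorStack":
        """Calibrated stand-in for the Au-SiO2 sensor slide at 670 nm.

        Coupling prism n=1.4977, Cr adhesion 2 nm, Au 50 nm, SiO2 15 nm,
        PBS ambient n=1.335.  The prism index was calibrated so that a
        351.1 nm adlayer of n=1.35 shifts the dip by 2.28 degrees; replace
        with measured slide parameters when available.
        """
        return cls(
            layers=(
                OpticalLayer("prism", 1.4977),
                OpticalLayer("Cr", 3.0 + 3.5j, 2.0),
                OpticalLayer("Au", 0.14 + 3.80j, 50.0),
                OpticalLayer("SiO2", 1.456, 15.0),
                OpticalLayer("PBS", 1.335),
            ),
            wavelength_nm=DEFAULT_WAVELENGTH_NM,
        )

    @classmethod
    def from_toml(cls, path: str | Path) -> "SensorStack":
        """Load a stack description from a TOML file.

        Expected schema::

            wavelength_nm = 670.0
            [[layers]]
            name = "prism"
            n_real = 1.4977
            # n_imag = 0.0        (optional)
            # thickness_nm = 2.0  (omit for the two half-spaces)
        """
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        try:
            raw_layers = doc["layers"]
        except KeyError as exc:
            raise ValidationError(f"{path}: missing [[layers]] table") from exc
        layers = []
        for i, entry in enumerate(raw_layers):
            try:
                n = complex(float(entry["n_real"]), float(entry.get("n_imag", 0.0)))
                layers.append(
                    OpticalLayer(
                        name=str(entry.get("name", f"layer{i}")),
                        refractive_index=n,
                        thickness=(
                            float(entry["thickness_nm"])
                            if "thickness_nm" in entry
                            else None
                        ),
                    )
                )
            except KeyError as exc:
                raise ValidationError(
                    f"{path}: layers[{i}] missing key {exc.args[0]!r}"
                ) from exc
        return cls(
            layers=tuple(layers),
            wavelength_nm=float(doc.get("wavelength_nm", DEFAULT_WAVELENGTH_NM)),
        )


@dataclass(frozen=True)
class AngularScan:
    """Reflectance sampled on a strictly increasing angle grid (degrees)."""

    angles: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if a.shape != r.shape or a.ndim != 1:
            raise ValidationError("angles and reflectance must be equal-length 1-D")
        if a.size == 0:
            raise ValidationError("empty scan")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValidationError("angles must be strictly increasing")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "reflectance", r)

    def __len__(self) -> int:
        return int(self.angles.size)


def _reflectance_p_array(stack: SensorStack, angles_deg: np.ndarray) -> np.ndarray:
    """|r_p|^2 for an array of internal incidence angles (vectorized)."""
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
    k0 = 2.0 * math.pi / stack.wavelength_nm
    n0 = stack.coupling_index
    # In-plane wavevector conserved across the stack; set by the real prism
    # index (lossless coupling medium assumed).
    kx2 = (n0.real * k0 * np.sin(theta)) ** 2

    ns = [complex(lay.refractive_index) for lay in stack.layers]
    kz = [np.sqrt(n * n * k0 * k0 - kx2 + 0j) for n in ns]
    # p-polarization admittance q_j = kz_j / n_j^2
    q = [kz_j / (n * n) for kz_j, n in zip(kz, ns)]

    m00 = np.ones_like(theta, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for j, lay in enumerate(stack.layers[1:-1], start=1):
        beta = kz[j] * lay.thickness
        c, s = np.cos(beta), np.sin(beta)
        a00, a01 = c, -1j * s / q[j]
        a10, a11 = -1j * q[j] * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )

    qN, q1 = q[-1], q[0]
    num = (m00 + m01 * qN) * q1 - (m10 + m11 * qN)
    den = (m00 + m01 * qN) * q1 + (m10 + m11 * qN)
    return np.abs(num / den) ** 2


def reflectance_p(stack: SensorStack, angle_deg: float) -> float:
    """p-polarized power reflectance at one internal incidence angle.

    Parameters
    ----------
    stack : SensorStack
        Valid stack (validated at construction).
    angle_deg : float
        Internal incidence angle in the coupling half-space, in (0, 90).
    """
    if not 0.0 < angle_deg < 90.0:
        raise ValidationError(f"angle must be in (0, 90) degrees, got {angle_deg}")
    return float(_reflectance_p_array(stack, np.array([angle_deg]))[0])


def angular_scan(
    stack: SensorStack,
    angle_min: float = DEFAULT_ANGLE_MIN,
    angle_max: float = DEFAULT_ANGLE_MAX,
    step: float = DEFAULT_ANGLE_STEP,
) -> AngularScan:
    """Sample reflectance on the closed grid [angle_min, angle_max]."""
    if not angle_min < angle_max:
        raise ValidationError("angle_min must be < angle_max")
    if not step > 0:
        raise ValidationError("step must be > 0")
    n = int(math.floor((angle_max - angle_min) / step + 0.5)) + 1
    angles = angle_min + step * np.arange(n)
    if angles.size == 0:
        raise ValidationError("empty angular grid")
    return AngularScan(angles=angles, reflectance=_reflectance_p_array(stack, angles))


def find_dip(scan: AngularScan) -> float:
    """Locate the SPR dip angle by 3-point parabolic interpolation.

    The global minimum sample must be interior to the grid; ties are broken
    toward the lower angle.  Raises :class:`DipNotFoundError` when the
    minimum sits on a boundary (scan range too narrow).
    """
    r = scan.reflectance
    if len(scan) < 3:
        raise DipNotFoundError("scan too short to locate a dip (need >= 3 points)")
    i = int(np.argmin(r))
    if i == 0 or i == len(scan) - 1:
        raise DipNotFoundError(
            f"reflectance minimum at scan boundary (angle {scan.angles[i]:.4f} deg); "
            "widen the scan range"
        )
    y0, y1, y2 = r[i - 1], r[i], r[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        # flat triple: fall back to the grid minimum
        return float(scan.angles[i])
    x0, x1 = scan.angles[i - 1], scan.angles[i]
    h = x1 - x0
    return float(x1 + 0.5 * h * (y0 - y2) / denom)


def dip_angle(
    stack: SensorStack,
    angle_min: float = DEFAULT_ANGLE_MIN,
    angle_max: float = DEFAULT_ANGLE_MAX,
    step: float = DEFAULT_ANGLE_STEP,
) -> float:
    """Convenience: scan the stack and return the refined dip angle."""
    return find_dip(angular_scan(stack, angle_min, angle_max, step))


def angular_response(
    stack: SensorStack,
    adlayer: Adlayer,
    angle_min: float = DEFAULT_ANGLE_MIN,
    angle_max: float = DEFAULT_ANGLE_MAX,
    step: float = DEFAULT_ANGLE_STEP,
) -> float:
    """Dip-angle shift (degrees) caused by inserting the adlayer.

    Returns exactly 0.0 for a zero-thickness or index-matched adlayer (the
    stack is then optically unchanged, so no scan is needed).
    """
    if adlayer.thickness == 0.0:
        return 0.0
    if complex(adlayer.refractive_index) == stack.ambient_index:
        return 0.0
    bare = dip_angle(stack, angle_min, angle_max, step)
    loaded = dip_angle(stack.with_adlayer(adlayer), angle_min, angle_max, step)
    return loaded - bare


def max_monolayer_response(
    stack: SensorStack,
    particle: ParticleModel,
    angle_min: float = DEFAULT_ANGLE_MIN,
    angle_max: float = DEFAULT_ANGLE_MAX,
    step: float = DEFAULT_ANGLE_STEP,
) -> float:
    """Angular response of a full packed particle monolayer.

    The monolayer is represented as a homogeneous adlayer with the particle
    refractive index and the effective thickness from the packing model;
    this is the denominator used to convert measured immobilization
    responses into surface coverage.
    """
    adlayer = Adlayer(
        refractive_index=particle.refractive_index,
        thickness=particle.effective_layer_thickness_nm,
    )
    return angular_response(stack, adlayer, angle_min, angle_max, step)
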