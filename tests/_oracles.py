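"""Independent reference implementations used only by the test suite.

The Parratt recursion below is written directly from the recursive Fresnel
formulation for stratified media and shares no code with the package's
transfer-matrix implementation.
"""

from __future__ import annotations

import cmath
import math


def parratt_reflectance_p(ns, ds, wavelength_nm, angle_deg):
    """|r_p|^2 by Parratt's recursion.

    Parameters
    ----------
    ns : sequence of complex
        Refractive indices from the incidence half-space to the exit
        half-space (length N).
    ds : sequence of float
        Thicknesses (nm) of the N-2 interior layers.
    wavelength_nm : float
    angle_deg : float
        Internal incidence angle in the first medium, degrees.
    """
    n_layers = len(ns)
    assert len(ds) == n_layers - 2
    k0 = 2.0 * math.pi / wavelength_nm
    kx = ns[0].real * k0 * math.sin(math.radians(angle_deg))
    kz = [cmath.sqrt((n * k0) ** 2 - kx * kx) for n in ns]

    def fresnel_p(j):
        # interface between layer j and j+1
        a = ns[j + 1] ** 2 * kz[j]
        b = ns[j] ** 2 * kz[j + 1]
        return (a - b) / (a + b)

    r = fresnel_p(n_layers - 2)
    for j in range(n_layers - 3, -1, -1):
        phase = cmath.exp(2j * kz[j + 1] * ds[j])  # ds[j] is thickness of layer j+1
        rj = fresnel_p(j)
        r = (rj + r * phase) / (1.0 + rj * r * phase)
    return abs(r) ** 2


def parabola_vertex(x0, x1, x2, y0, y1, y2):
    """x-coordinate of the vertex of the parabola through three points."""
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    return -b / (2.0 * a)
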