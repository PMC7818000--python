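"""Gaussian beam propagation through the same ABCD matrices.

A coherent TEM00 beam is tracked by its complex curvature parameter q,
defined through 1/q = 1/R - i lambda / (pi n w^2) where R is the
wavefront radius of curvature (mm), w the 1/e^2 field radius (mm), lambda
the vacuum wavelength (mm) and n the local refractive index.  At the
waist q = i z_R with z_R the Rayleigh range.  Any element transforms the
beam with the bilinear law q' = (A q + B) / (C q + D).

The q parameter follows the physical-angle matrix convention of
:mod:`paraxial.matrices`; the refractive index enters through interface
matrices and through the w-recovery formula above.  Apertures never clip
a Gaussian beam (clipping is a ray-ensemble concept here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .matrices import TransferMatrix

__all__ = ["GaussianBeam", "BeamParameters", "propagate_beam", "beam_parameters"]


@dataclass(frozen=True)
class GaussianBeam:
    """A coherent beam state: complex q (mm), vacuum wavelength (mm),
    local index and axial position."""

    q: complex
    wavelength: float
    n: float = 1.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.q.imag == 0:
            raise ValueError("physical beams require Im(q) != 0")

    @classmethod
    def from_waist(
        cls, w0: float, wavelength: float, n: float = 1.0, z: float = 0.0
    ) -> "GaussianBeam":
        """Beam at its waist of radius ``w0``: q = i pi n w0^2 / lambda."""
        if w0 <= 0:
            raise ValueError("waist radius must be > 0")
        zr = math.pi * n * w0 * w0 / wavelength
        return cls(q=complex(0.0, zr), wavelength=wavelength, n=n, z=z)


@dataclass(frozen=True)
class BeamParameters:
    """Derived beam geometry: radius w, wavefront curvature R, waist w0 and
    signed distance from the current plane to the waist (positive when the
    waist lies downstream)."""

    w: float
    R: float
    w0: float
    z_to_waist: float


def propagate_beam(M: TransferMatrix, beam: GaussianBeam) -> GaussianBeam:
    """q' = (A q + B) / (C q + D); z advances by the element's length."""
    denom = M.C * beam.q + M.D
    if abs(denom) == 0.0:
        raise ValueError("beam focused to a point at the exit plane (C q + D = 0)")
    return GaussianBeam(
        q=(M.A * beam.q + M.B) / denom,
        wavelength=beam.wavelength,
        n=M.n_back,
        z=beam.z + M.L,
    )


def beam_parameters(beam: GaussianBeam) -> BeamParameters:
    """Invert 1/q = 1/R - i lambda/(pi n w^2) for the standard beam
    geometry."""
    inv_q = 1.0 / beam.q
    R = math.inf if inv_q.real == 0.0 else 1.0 / inv_q.real
    w = math.sqrt(-beam.wavelength / (math.pi * beam.n * inv_q.imag))
    zr = beam.q.imag
    w0 = math.sqrt(abs(zr) * beam.wavelength / (math.pi * beam.n))
    return BeamParameters(w=w, R=R, w0=w0, z_to_waist=-beam.q.real)
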