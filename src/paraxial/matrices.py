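"""Rays and ray-transfer (ABCD) matrices in the paraxial approximation.

A ray at axial position ``z`` is a height ``y`` (mm, positive above the
axis) and a physical angle ``theta`` (rad) with respect to the optical
axis.  In the small-angle regime every optical element acts linearly on
``(y, theta)`` and is represented by a 2x2 matrix::

    [y']   [A  B] [y]
    [th'] = [C  D] [th]

Conventions used throughout the package:

* light travels toward +z; all lengths in millimetres, angles in radians;
* a radius of curvature R is positive when its centre of curvature lies
  after (downstream of) the surface;
* angles are *physical* angles, never reduced (n-multiplied) angles.  The
  refractive index therefore enters only through dielectric interfaces,
  and the determinant of any matrix is ``n_front / n_back``;
* ``theta`` is a paraxial angle: no trigonometric transform is ever
  applied to it inside the engine.

Blocking by a finite clear aperture is not a linear operation and is
handled as ray *state*: :func:`transform` marks a ray blocked when it
arrives at the entrance plane of an element outside the clear diameter
(the edge itself transmits), and a blocked ray is frozen thereafter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "IMAGING_TOLERANCE",
    "Ray",
    "TransferMatrix",
    "SystemProperties",
    "make_space",
    "make_thin_lens",
    "make_dielectric_interface",
    "make_thick_lens",
    "make_aperture",
    "compose",
    "transform",
    "system_properties",
    "optical_invariant",
    "gauss_image_solve",
]

#: |B| below this (mm) declares an imaging (conjugate) condition.  Chosen so
#: that floating-point products of exact conjugate distances still qualify.
IMAGING_TOLERANCE = 1e-9

_DET_TOLERANCE = 1e-8


@dataclass(frozen=True)
class Ray:
    """Paraxial ray state.

    Attributes
    ----------
    y : float
        Height above the optical axis (mm).
    theta : float
        Angle with the optical axis (rad, paraxial).
    z : float
        Axial position (mm).
    blocked : bool
        Whether a finite aperture has stopped this ray.  Once set, ``y``
        and ``theta`` stay frozen at their values at the blocking plane.
    blocked_at : float or None
        Axial position of the blocking aperture (mm), when blocked.
    """

    y: float
    theta: float
    z: float = 0.0
    blocked: bool = False
    blocked_at: float | None = None


@dataclass(frozen=True)
class TransferMatrix:
    """An ABCD element (or composed group) with physical bookkeeping.

    ``L`` is the physical length along the axis spanned by the element,
    ``n_front``/``n_back`` the refractive indices before and after it, and
    ``aperture_diameter`` its clear diameter (``math.inf`` when the element
    does not clip rays).  Units: B in mm, C in 1/mm, A and D dimensionless.
    """

    A: float
    B: float
    C: float
    D: float
    L: float = 0.0
    n_front: float = 1.0
    n_back: float = 1.0
    aperture_diameter: float = math.inf
    label: str = ""

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError(f"physical length L must be >= 0, got {self.L}")
        if self.n_front < 1 or self.n_back < 1:
            raise ValueError("refractive indices must be >= 1")
        if not self.aperture_diameter > 0:
            raise ValueError(
                f"aperture_diameter must be > 0, got {self.aperture_diameter}"
            )
        # General ray-matrix identity: det = n_front/n_back (1 when the
        # surrounding media match).  Scale-aware to tolerate rounding in
        # long products.
        scale = max(1.0, abs(self.A * self.D), abs(self.B * self.C))
        if abs(self.determinant - self.n_front / self.n_back) > _DET_TOLERANCE * scale:
            raise ValueError(
                "determinant A*D - B*C must equal n_front/n_back "
                f"(got {self.determinant}, expected {self.n_front / self.n_back})"
            )

    @property
    def determinant(self) -> float:
        return self.A * self.D - self.B * self.C

    @property
    def has_finite_aperture(self) -> bool:
        return math.isfinite(self.aperture_diameter)


@dataclass(frozen=True)
class SystemProperties:
    """Closed-form cardinal properties of a composed system.

    Principal planes are planes of unity magnification from which focal
    lengths are measured; they are located ``(n_front/n_back - D)/C`` after
    the entrance plane and ``(1 - A)/C`` after the exit plane.  Focal
    distances are measured from the entrance/exit reference planes.  For an
    afocal system (C = 0) all focal quantities are infinite.
    """

    efl_front: float
    efl_back: float
    front_focal_distance: float
    back_focal_distance: float
    principal_plane_front: float
    principal_plane_back: float
    is_imaging: bool
    transverse_magnification: float | None
    angular_magnification: float | None


# ---------------------------------------------------------------------------
# element constructors


def make_space(d: float, n: float = 1.0, label: str = "") -> TransferMatrix:
    """Free propagation over distance ``d`` (mm) in a medium of index ``n``.

    Because angles are physical, the matrix is [[1, d], [0, 1]] regardless
    of ``n``; the index only matters for adjacency bookkeeping.
    """
    if d < 0:
        raise ValueError(f"propagation distance must be >= 0, got {d}")
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    return TransferMatrix(1.0, d, 0.0, 1.0, L=d, n_front=n, n_back=n, label=label)


def make_thin_lens(f: float, diameter: float = math.inf, label: str = "") -> TransferMatrix:
    """Thin lens of focal length ``f`` (mm): [[1, 0], [-1/f, 1]]."""
    if f == 0:
        raise ValueError("focal length must be nonzero")
    return TransferMatrix(
        1.0, 0.0, -1.0 / f, 1.0, L=0.0, aperture_diameter=diameter, label=label
    )


def make_dielectric_interface(
    R: float,
    n1: float,
    n2: float,
    diameter: float = math.inf,
    label: str = "",
) -> TransferMatrix:
    """Refraction at a spherical interface of radius ``R`` between indices
    ``n1`` and ``n2`` (paraxial Snell): [[1, 0], [(n1-n2)/(n2 R), n1/n2]].

    ``R = math.inf`` gives a flat interface (C = 0).
    """
    if R == 0:
        raise ValueError("radius of curvature must be nonzero (use math.inf for flat)")
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    C = 0.0 if math.isinf(R) else (n1 - n2) / (n2 * R)
    return TransferMatrix(
        1.0, 0.0, C, n1 / n2, L=0.0, n_front=n1, n_back=n2,
        aperture_diameter=diameter, label=label,
    )


def make_thick_lens(
    n: float,
    R1: float,
    R2: float,
    t: float,
    diameter: float = math.inf,
    label: str = "",
) -> TransferMatrix:
    """Thick lens in air: interface(R1, 1->n), glass of thickness ``t``,
    interface(R2, n->1).  Its effective focal length -1/C reproduces the
    thick-lens Lensmaker equation
    1/f = (n-1) [1/R1 - 1/R2 + (n-1) t / (n R1 R2)].
    """
    if t < 0:
        raise ValueError("center thickness must be >= 0")
    composed = compose(
        [
            make_dielectric_interface(R1, 1.0, n, diameter=diameter),
            make_space(t, n),
            make_dielectric_interface(R2, n, 1.0, diameter=diameter),
        ]
    )
    return replace(composed, aperture_diameter=diameter, label=label)


def make_aperture(diameter: float, label: str = "") -> TransferMatrix:
    """A pure clear aperture: the identity matrix with a finite diameter.

    It acts on rays only through the blocking rule (|y| > diameter/2 at its
    plane marks the ray blocked; the edge itself transmits).
    """
    if not diameter > 0:
        raise ValueError(f"aperture diameter must be > 0, got {diameter}")
    return TransferMatrix(
        1.0, 0.0, 0.0, 1.0, L=0.0, aperture_diameter=diameter, label=label
    )


# ---------------------------------------------------------------------------
# composition and transformation


def compose(elements: Sequence[TransferMatrix]) -> TransferMatrix:
    """Compose elements in propagation order (first element hit first).

    Matrices multiply right-to-left (the first element is the rightmost
    factor).  Physical lengths add; adjacent media must match.  The
    composed matrix carries no clear aperture: blocking is a per-element
    property that does not compose linearly.
    """
    if len(elements) == 0:
        raise ValueError("compose() requires at least one element")
    result = elements[0]
    for el in elements[1:]:
        if abs(el.n_front - result.n_back) > 1e-9:
            raise ValueError(
                f"refractive-index mismatch between adjacent elements: "
                f"{result.n_back} -> {el.n_front}"
            )
        result = TransferMatrix(
            A=el.A * result.A + el.B * result.C,
            B=el.A * result.B + el.B * result.D,
            C=el.C * result.A + el.D * result.C,
            D=el.C * result.B + el.D * result.D,
            L=result.L + el.L,
            n_front=result.n_front,
            n_back=el.n_back,
        )
    return result


def transform(M: TransferMatrix, r: Ray) -> Ray:
    """Apply one element to a ray.

    A blocked ray passes through unchanged and stays blocked.  For an
    element with a finite clear aperture the blocking rule is applied at
    the entrance plane before the matrix: rays with |y| strictly greater
    than half the diameter are blocked there (edge-inclusive transmission,
    so marginal rays that graze the stop edge trace as transmitted).
    """
    if r.blocked:
        return r
    if M.has_finite_aperture and abs(r.y) > M.aperture_diameter * 0.5:
        return replace(r, blocked=True, blocked_at=r.z)
    return Ray(
        y=M.A * r.y + M.B * r.theta,
        theta=M.C * r.y + M.D * r.theta,
        z=r.z + M.L,
    )


def system_properties(
    M: TransferMatrix, tol: float = IMAGING_TOLERANCE
) -> SystemProperties:
    """Cardinal points and imaging status of a (composed) matrix.

    Back effective focal length is -1/C and front is -(n_front/n_back)/C;
    the back focal distance (exit plane to back focal point) is -A/C and
    the front focal distance (n_front/n_back)(-D/C), consistent with the
    determinant convention.  ``is_imaging`` holds when |B| < ``tol``; the
    transverse and angular magnifications are then A and D.
    """
    ratio = M.n_front / M.n_back
    if M.C != 0.0:
        efl_back = -1.0 / M.C
        efl_front = -ratio / M.C
        bfd = -M.A / M.C
        ffd = ratio * (-M.D / M.C)
        ppf = (ratio - M.D) / M.C
        ppb = (1.0 - M.A) / M.C
    else:  # afocal: focal quantities at infinity, not an error
        efl_back = efl_front = bfd = ffd = ppf = ppb = math.inf
    is_imaging = abs(M.B) < tol
    return SystemProperties(
        efl_front=efl_front,
        efl_back=efl_back,
        front_focal_distance=ffd,
        back_focal_distance=bfd,
        principal_plane_front=ppf,
        principal_plane_back=ppb,
        is_imaging=is_imaging,
        transverse_magnification=M.A if is_imaging else None,
        angular_magnification=M.D if is_imaging else None,
    )


def optical_invariant(n: float, r1: Ray, r2: Ray) -> float:
    """The optical invariant n (y1 th2 - y2 th1) of two co-located rays.

    Conserved through any unblocked paraxial system; maximal (and called
    the Lagrange invariant H) for the principal/axial ray pair.
    """
    if abs(r1.z - r2.z) > 1e-9:
        raise ValueError(
            f"optical invariant requires rays at the same z ({r1.z} != {r2.z})"
        )
    return n * (r1.y * r2.theta - r2.y * r1.theta)


def gauss_image_solve(f: float, do: float) -> tuple[float, float]:
    """Image distance and magnification for a thin lens.

    Solves B = 0 for the system space(do) + lens(f) + space(di), whose B
    element is ``do + di (1 - do/f)`` — linear in di.  The solution
    satisfies Gauss's law 1/do + 1/di = 1/f; the magnification is the A
    element of the composed matrix, 1 - di/f.  ``do = f`` images to
    infinity, reported as (inf, inf).
    """
    if f == 0:
        raise ValueError("focal length must be nonzero")
    coeff = 1.0 - do / f
    if coeff == 0.0:
        return math.inf, math.inf
    di = -do / coeff
    return di, 1.0 - di / f
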