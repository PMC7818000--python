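"""Sequential optical systems with an object plane: tracing, stops, special
rays, invariants and conjugate planes.

An :class:`ImagingPath` is an ordered list of elements with the object
plane at z = 0; element positions are cumulative sums of the physical
lengths.  The defining apertures are found from two test rays, exploiting
linearity instead of the literal scan-until-blocked procedure (the two are
equivalent, which the test suite checks against a brute-force scanner):

* **aperture stop (AS)** — trace the on-axis ray (y=0, theta=1); the AS is
  the finite-aperture element maximizing |y| / (D/2).  The *axial ray* is
  this test ray rescaled to graze the AS edge; its angle sets the
  object-space NA.
* **field stop (FS)** — trace the unit chief ray (from y0=1 through the AS
  centre); the FS is the finite aperture maximizing the same ratio (the AS
  itself cannot win, the chief ray having zero height there).  The
  *principal ray* is the chief ray rescaled to graze the FS edge; its
  origin height is half the field of view.

Ties between equally limiting apertures go to the smallest z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NoApertureStop, NoFieldStop, StopConjugateToObject
from .matrices import (
    IMAGING_TOLERANCE,
    Ray,
    TransferMatrix,
    compose,
    optical_invariant,
    transform,
)

__all__ = [
    "ImagingPath",
    "StopInfo",
    "TraceRecord",
    "ConjugatePlane",
    "trace",
    "aperture_stop",
    "axial_ray",
    "marginal_rays",
    "chief_ray",
    "field_stop",
    "principal_ray",
    "field_of_view",
    "lagrange_invariant",
    "intermediate_conjugates",
]

_RATIO_EPS = 1e-12  # tie window for limiting-aperture ratios
_CONJ_EPS = 1e-12   # |B| below this counts as "conjugate to object" in solvers


@dataclass
class ImagingPath:
    """Ordered element sequence with the object plane at z = 0.

    ``object_height`` is the full height of the nominal object (mm) and
    ``object_index`` the refractive index at the object plane.
    """

    elements: list[TransferMatrix] = field(default_factory=list)
    object_height: float = 10.0
    object_index: float = 1.0
    label: str = ""

    def append(self, element) -> "ImagingPath":
        """Append one element or an iterable of elements; returns self."""
        if isinstance(element, TransferMatrix):
            self.elements.append(element)
        else:
            self.elements.extend(element)
        return self

    @property
    def length(self) -> float:
        """Total physical length of the path (mm)."""
        return sum(el.L for el in self.elements)

    def transfer_matrix(self) -> TransferMatrix:
        """The composed object-to-exit matrix."""
        self._require_elements()
        return compose(self.elements)

    def entrance_states(self):
        """(z, cumulative object->entrance matrix, element) per element."""
        self._require_elements()
        z = 0.0
        M = TransferMatrix(
            1.0, 0.0, 0.0, 1.0, n_front=self.object_index, n_back=self.object_index
        )
        states = []
        for el in self.elements:
            states.append((z, M, el))
            M = compose([M, el])
            z += el.L
        return states

    def _require_elements(self) -> None:
        if not self.elements:
            raise ValueError("imaging path has no elements")


@dataclass(frozen=True)
class StopInfo:
    """Position, clear diameter and identity of a limiting aperture."""

    z: float
    diameter: float
    label: str
    index: int


@dataclass(frozen=True)
class TraceRecord:
    """Ray states (z, y, theta) at the object plane and after every element.

    Once the ray is blocked, later samples keep the frozen (y, theta) while
    z continues to advance with the geometry.
    """

    samples: list[tuple[float, float, float]]
    blocked: bool
    blocked_at: float | None
    blocked_index: int | None


@dataclass(frozen=True)
class ConjugatePlane:
    """A plane conjugate to the object (|B| < tolerance), with the
    transverse magnification A of the object-to-plane matrix."""

    z: float
    magnification: float


def trace(path: ImagingPath, r: Ray) -> TraceRecord:
    """Trace one ray from the object plane through every element.

    Blocking (at the first finite aperture with |y| > D/2, edge
    transmitting) is a recorded state, not an error.
    """
    path._require_elements()
    if abs(r.z) > 1e-12:
        raise ValueError("trace() expects a ray at the object plane (z = 0)")
    ray = r
    z = 0.0
    samples = [(z, ray.y, ray.theta)]
    blocked_index: int | None = None
    for i, el in enumerate(path.elements):
        was_blocked = ray.blocked
        ray = transform(el, ray)
        if ray.blocked and not was_blocked:
            blocked_index = i
        z += el.L
        samples.append((z, ray.y, ray.theta))
    return TraceRecord(samples, ray.blocked, ray.blocked_at, blocked_index)


def _aperture_stop_state(path: ImagingPath):
    """AS StopInfo plus the object->AS entrance matrix."""
    best = None
    for i, (z, M, el) in enumerate(path.entrance_states()):
        if not el.has_finite_aperture:
            continue
        # height of the axial test ray (y=0, theta=1) at this plane is B
        ratio = abs(M.B) / (el.aperture_diameter * 0.5)
        if best is None or ratio > best[0] + _RATIO_EPS:
            best = (ratio, StopInfo(z, el.aperture_diameter, el.label, i), M)
    if best is None:
        raise NoApertureStop("no aperture stop: the path has no finite aperture")
    return best[1], best[2]


def aperture_stop(path: ImagingPath) -> StopInfo:
    """The finite aperture most limiting for the on-axis bundle."""
    return _aperture_stop_state(path)[0]


def axial_ray(path: ImagingPath) -> Ray:
    """The on-axis ray grazing the AS edge (largest transmitted angle)."""
    stop, M = _aperture_stop_state(path)
    if abs(M.B) < _CONJ_EPS:
        raise StopConjugateToObject(
            "aperture stop conjugate to object: axial ray angle is unbounded"
        )
    return Ray(0.0, (stop.diameter * 0.5) / abs(M.B))


def marginal_rays(path: ImagingPath, y0: float = 0.0) -> tuple[Ray, Ray]:
    """The two rays from object height ``y0`` reaching the AS edges +-D/2.

    Solved linearly from the object->AS submatrix: theta = (+-D/2 - A y0)/B.
    For y0 = 0 this reduces to the +-axial ray pair.
    """
    stop, M = _aperture_stop_state(path)
    if abs(M.B) < _CONJ_EPS:
        raise StopConjugateToObject(
            "aperture stop conjugate to object: marginal rays are not defined"
        )
    half = stop.diameter * 0.5
    up = Ray(y0, (half - M.A * y0) / M.B)
    down = Ray(y0, (-half - M.A * y0) / M.B)
    return up, down


def chief_ray(path: ImagingPath, y0: float) -> Ray:
    """The ray from object height ``y0`` through the AS centre."""
    _, M = _aperture_stop_state(path)
    if abs(M.B) < _CONJ_EPS:
        raise StopConjugateToObject(
            "object is conjugate to the aperture stop: chief ray undefined"
        )
    return Ray(y0, -M.A * y0 / M.B)


def _field_stop_state(path: ImagingPath):
    """FS StopInfo plus the unit chief ray's height at the FS plane."""
    unit_chief = chief_ray(path, 1.0)
    best = None
    for i, (z, M, el) in enumerate(path.entrance_states()):
        if not el.has_finite_aperture:
            continue
        h = M.A + M.B * unit_chief.theta  # unit chief height at this plane
        ratio = abs(h) / (el.aperture_diameter * 0.5)
        if ratio <= 1e-9:
            continue  # crossed on-axis (the AS, or a degenerate coincidence)
        if best is None or ratio > best[0] + _RATIO_EPS:
            best = (ratio, StopInfo(z, el.aperture_diameter, el.label, i), h)
    if best is None:
        raise NoFieldStop("infinite field of view: no aperture limits the chief ray")
    return best[1], best[2]


def field_stop(path: ImagingPath) -> StopInfo:
    """The finite aperture most limiting for chief rays (field of view)."""
    return _field_stop_state(path)[0]


def principal_ray(path: ImagingPath) -> Ray:
    """The extreme chief ray, grazing the FS edge; its origin height is the
    half field of view."""
    fs, h_unit = _field_stop_state(path)
    y0 = (fs.diameter * 0.5) / abs(h_unit)
    return chief_ray(path, y0)


def field_of_view(path: ImagingPath) -> float:
    """Full field of view at the object plane (mm): twice the principal-ray
    origin height."""
    return 2.0 * principal_ray(path).y


def lagrange_invariant(path: ImagingPath) -> float:
    """H = n (y_p theta_a - y_a theta_p) over the principal/axial pair,
    evaluated at the object plane and reported positive."""
    p = principal_ray(path)
    a = axial_ray(path)
    return abs(optical_invariant(path.object_index, p, a))


def _is_pure_space(el: TransferMatrix) -> bool:
    return (
        el.A == 1.0
        and el.C == 0.0
        and el.D == 1.0
        and el.B == el.L
        and not el.has_finite_aperture
    )


def intermediate_conjugates(
    path: ImagingPath,
    interior: bool = False,
    tol: float = IMAGING_TOLERANCE,
) -> list[ConjugatePlane]:
    """Planes conjugate to the object (z > 0), each with its magnification.

    By default only element boundaries are examined.  With
    ``interior=True`` conjugates falling inside free-space segments are
    also solved for (B varies linearly along a space: B(s) = B0 + s D0),
    which locates images that do not coincide with an element plane.
    """
    path._require_elements()
    planes: list[ConjugatePlane] = []

    def _push(z: float, mag: float) -> None:
        if z <= 1e-12:
            return
        if planes and abs(planes[-1].z - z) < 1e-9:
            planes[-1] = ConjugatePlane(z, mag)
        else:
            planes.append(ConjugatePlane(z, mag))

    z = 0.0
    M = TransferMatrix(
        1.0, 0.0, 0.0, 1.0, n_front=path.object_index, n_back=path.object_index
    )
    for el in path.elements:
        if interior and el.L > 0 and _is_pure_space(el) and M.D != 0.0:
            s = -M.B / M.D
            if 1e-9 < s < el.L - 1e-9:
                _push(z + s, M.A + s * M.C)
        M = compose([M, el])
        z += el.L
        if abs(M.B) < tol:
            _push(z, M.A)
    return planes
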