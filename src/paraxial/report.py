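"""Two-ray decomposition, blocked-vs-vignetted classification and the
system efficiency report.

Any ray can be written as a linear combination of the principal and axial
rays, because those two have a nonzero optical invariant and therefore
span the (y, theta) plane.  Writing H for the Lagrange invariant of the
pair, Cramer's rule on the 2x2 system gives the weights

    a = n (y th_a - y_a th) / H      (principal-ray weight)
    b = n (y_p th - y th_p) / H      (axial-ray weight)

Both coefficients are ratios of optical invariants, so they are conserved
along any unblocked trace: a ray's (a, b) is a property of the ray, not of
the plane where it is evaluated.

That conservation is what turns the coefficients into a vignetting
diagnostic.  A ray with max(|a|, |b|) > 1 lies outside the design envelope
spanned by the principal and axial rays and is *expected* to be blocked; a
ray inside the envelope (max(|a|, |b|) <= 1, boundary included) that is
nonetheless blocked reveals an element clipping the nominal bundle —
vignetting — and the offending element is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, DegenerateBasis
from .ensembles import RayEnsemble, trace_arrays
from .matrices import Ray, optical_invariant
from .path import (
    ImagingPath,
    StopInfo,
    aperture_stop,
    axial_ray,
    field_of_view,
    field_stop,
    principal_ray,
)

__all__ = [
    "DecompositionCoefficients",
    "Classification",
    "EfficiencyReport",
    "TRANSMITTED",
    "EXPECTED_BLOCKED",
    "VIGNETTED",
    "decompose",
    "classify_rays",
    "report_efficiency",
]

TRANSMITTED = "transmitted"
EXPECTED_BLOCKED = "expected_blocked"
VIGNETTED = "vignetted"


@dataclass(frozen=True)
class DecompositionCoefficients:
    """Weights (a, b) of a ray on the (principal, axial) basis."""

    a: float
    b: float


def decompose(
    r: Ray, principal: Ray, axial: Ray, n: float = 1.0
) -> DecompositionCoefficients:
    """Solve r = a * principal + b * axial (exact reconstruction).

    All three rays must sit at the same z, and the basis must be
    non-degenerate (H != 0).
    """
    H = optical_invariant(n, principal, axial)
    if H == 0.0:
        raise DegenerateBasis(
            "principal and axial rays are linearly dependent (H = 0)"
        )
    if abs(r.z - principal.z) > 1e-9:
        raise ValueError("ray and basis must be at the same z")
    a = n * (r.y * axial.theta - axial.y * r.theta) / H
    b = n * (principal.y * r.theta - r.y * principal.theta) / H
    return DecompositionCoefficients(a, b)


def _decompose_arrays(ys, thetas, principal: Ray, axial: Ray, n: float):
    H = n * (principal.y * axial.theta - axial.y * principal.theta)
    if H == 0.0:
        raise DegenerateBasis("principal and axial rays are linearly dependent (H = 0)")
    a = n * (ys * axial.theta - axial.y * thetas) / H
    b = n * (principal.y * thetas - ys * principal.theta) / H
    return a, b


@dataclass(frozen=True)
class Classification:
    """Per-ray status plus the decomposition weights and blocking element."""

    status: np.ndarray
    a: np.ndarray
    b: np.ndarray
    blocked_index: np.ndarray


def classify_rays(path: ImagingPath, ensemble: RayEnsemble) -> Classification:
    """Classify every ray as transmitted, expected-blocked or vignetted.

    Each ray is decomposed on the principal/axial basis at the object
    plane; blocked rays within the design envelope (max(|a|, |b|) <= 1)
    are vignetted, the rest of the blocked rays were expected to be lost.
    """
    p = principal_ray(path)
    ax = axial_ray(path)
    a, b = _decompose_arrays(ensemble.ys, ensemble.thetas, p, ax, path.object_index)
    _, _, blocked, _, blocked_index, _ = trace_arrays(path, ensemble.ys, ensemble.thetas)
    outside = np.maximum(np.abs(a), np.abs(b)) > 1.0
    status = np.full(ensemble.count, TRANSMITTED, dtype=object)
    status[blocked & outside] = EXPECTED_BLOCKED
    status[blocked & ~outside] = VIGNETTED
    return Classification(status=status, a=a, b=b, blocked_index=blocked_index)


@dataclass(frozen=True)
class EfficiencyReport:
    """Aggregate throughput diagnosis of a path under a ray ensemble.

    Counts satisfy transmitted + vignetted + expected_blocked = total.
    ``vignetting_element`` names the element blocking the most vignetted
    rays (None when there is no vignetting).  ``notes`` records analysis
    steps that could not be completed (e.g. a path with no aperture stop).
    """

    aperture_stop: StopInfo | None
    field_stop: StopInfo | None
    fov: float | None
    object_na: float | None
    lagrange_h: float | None
    per_element_blocked_counts: dict[str, int]
    vignetted_count: int
    expected_blocked_count: int
    transmitted_count: int
    total_count: int
    vignetting_element: str | None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def _stop(s: StopInfo | None):
            if s is None:
                return None
            return {"z": s.z, "diameter": s.diameter, "label": s.label,
                    "index": s.index}

        return {
            "apertureStop": _stop(self.aperture_stop),
            "fieldStop": _stop(self.field_stop),
            "fov": self.fov,
            "objectNA": self.object_na,
            "lagrangeH": self.lagrange_h,
            "perElementBlockedCounts": dict(self.per_element_blocked_counts),
            "vignettedCount": self.vignetted_count,
            "expectedBlockedCount": self.expected_blocked_count,
            "transmittedCount": self.transmitted_count,
            "totalCount": self.total_count,
            "vignettingElement": self.vignetting_element,
            "notes": list(self.notes),
        }

    def to_text(self) -> str:
        lines = ["Efficiency report", "================="]

        def _stop_line(name: str, s: StopInfo | None) -> str:
            if s is None:
                return f"{name}: not found"
            tag = f" ({s.label})" if s.label else ""
            return f"{name}: z = {s.z:g} mm, diameter = {s.diameter:g} mm{tag}"

        lines.append(_stop_line("Aperture stop", self.aperture_stop))
        lines.append(_stop_line("Field stop", self.field_stop))
        if self.fov is not None:
            lines.append(f"Field of view (object): {self.fov:g} mm")
        if self.object_na is not None:
            lines.append(f"Object-space NA: {self.object_na:.6g}")
        if self.lagrange_h is not None:
            lines.append(f"Lagrange invariant H: {self.lagrange_h:.6g} mm*rad")
        lines.append(
            f"Rays: {self.total_count} total, {self.transmitted_count} transmitted, "
            f"{self.expected_blocked_count} expected blocked, "
            f"{self.vignetted_count} vignetted"
        )
        if self.per_element_blocked_counts:
            lines.append("Blocked per element:")
            for name, count in self.per_element_blocked_counts.items():
                lines.append(f"  {name}: {count}")
        if self.vignetting_element is not None:
            lines.append(f"Vignetting caused by: {self.vignetting_element}")
        for note in self.notes:
            lines.append(f"Note: {note}")
        return "\n".join(lines)


def _element_key(path: ImagingPath, index: int) -> str:
    el = path.elements[index]
    name = el.label if el.label else "element"
    return f"[{index}] {name}"


def report_efficiency(path: ImagingPath, ensemble: RayEnsemble) -> EfficiencyReport:
    """Aggregate stop info, FOV, NA, Lagrange invariant and ray tallies.

    Structural analysis failures (no aperture stop, unbounded field of
    view) degrade gracefully: the corresponding fields are None, a note is
    recorded, and blocked rays are tallied as expected losses since no
    design envelope exists to define vignetting.
    """
    if ensemble.count == 0:
        raise ValueError("cannot report efficiency for an empty ensemble")
    notes: list[str] = []
    as_info = fs_info = None
    fov = na = h_val = None
    classification = None
    try:
        as_info = aperture_stop(path)
        fs_info = field_stop(path)
        fov = field_of_view(path)
        ax = axial_ray(path)
        na = path.object_index * float(np.sin(ax.theta))
        p = principal_ray(path)
        h_val = abs(optical_invariant(path.object_index, p, ax))
        classification = classify_rays(path, ensemble)
    except AnalysisError as exc:
        notes.append(str(exc))

    if classification is None:
        _, _, blocked, _, blocked_index, _ = trace_arrays(
            path, ensemble.ys, ensemble.thetas
        )
        status = np.full(ensemble.count, TRANSMITTED, dtype=object)
        status[blocked] = EXPECTED_BLOCKED
        classification = Classification(
            status=status,
            a=np.full(ensemble.count, np.nan),
            b=np.full(ensemble.count, np.nan),
            blocked_index=blocked_index,
        )

    status = classification.status
    blocked_index = classification.blocked_index
    transmitted = int(np.count_nonzero(status == TRANSMITTED))
    vignetted = int(np.count_nonzero(status == VIGNETTED))
    expected = int(np.count_nonzero(status == EXPECTED_BLOCKED))

    per_element: dict[str, int] = {}
    for idx in np.unique(blocked_index[blocked_index >= 0]):
        per_element[_element_key(path, int(idx))] = int(
            np.count_nonzero(blocked_index == idx)
        )

    vignetting_element = None
    vignetted_idx = blocked_index[status == VIGNETTED]
    if vignetted_idx.size:
        values, counts = np.unique(vignetted_idx, return_counts=True)
        vignetting_element = _element_key(path, int(values[np.argmax(counts)]))

    return EfficiencyReport(
        aperture_stop=as_info,
        field_stop=fs_info,
        fov=fov,
        object_na=na,
        lagrange_h=h_val,
        per_element_blocked_counts=per_element,
        vignetted_count=vignetted,
        expected_blocked_count=expected,
        transmitted_count=transmitted,
        total_count=ensemble.count,
        vignetting_element=vignetting_element,
        notes=tuple(notes),
    )
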