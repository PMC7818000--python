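"""Worked microscope systems used as fixtures and documentation examples.

Three instruments are modelled:

* a confocal laser scanning microscope (CLSM) detection path ending at the
  pinhole, used to study pinhole sizing and optical sectioning;
* the CLSM scan relay from the polygonal scan mirror to the sample, used
  to map scan angle to focal-spot position;
* a Koehler illumination train, whose defining property is that source
  conjugates and sample conjugates never coincide;
* a widefield 4f imaging system with a camera, in three lens-diameter
  scenarios that move the aperture and field stops around.

Convenience builders ``system_4f`` and ``system_2f`` expand to their
primitive space/lens sequences so that stop detection sees every physical
surface.  An infinity-corrected objective is modelled as a focal-plane to
focal-plane black box [[0, f], [-1/f, 0]] stretched over its physical
focus-to-focus length, with the back aperture as its only clear-diameter
constraint — the minimal paraxial model consistent with a vendor
datasheet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ensembles import random_uniform_rays, trace_arrays
from .matrices import TransferMatrix, make_aperture, make_space, make_thin_lens
from .path import ImagingPath, intermediate_conjugates

__all__ = [
    "ObjectiveModel",
    "OLYMPUS_UISUPLAPO60XW",
    "system_2f",
    "system_4f",
    "build_clsm_detection_path",
    "clsm_detection_magnification",
    "optimal_pinhole_diameter",
    "transmission_vs_defocus",
    "DEFAULT_DEFOCUS_POSITIONS_MM",
    "build_scan_path",
    "scan_positions",
    "build_kohler_path",
    "KOHLER_SAMPLE_Z",
    "kohler_conjugates",
    "build_widefield_path",
    "WIDEFIELD_SCENARIOS",
    "CLSM_FOCAL_RADIUS_MM",
]

#: focal-spot radius at the CLSM sample (mm): a 0.5 um diameter spot.
CLSM_FOCAL_RADIUS_MM = 0.000250


@dataclass(frozen=True)
class ObjectiveModel:
    """A vendor objective reduced to its paraxial black box.

    ``f`` is the effective focal length (mm), ``focus_to_focus_length``
    the physical span between the front and back focal planes, and
    ``back_aperture`` the clear diameter at the back (mm).  The remaining
    datasheet numbers are carried for reference.
    """

    f: float
    na: float
    focus_to_focus_length: float
    back_aperture: float
    working_distance: float
    magnification: float
    field_number: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("objective focal length must be > 0")

    def as_matrix(self) -> TransferMatrix:
        """Front focal plane to back focal plane: [[0, f], [-1/f, 0]]."""
        return TransferMatrix(
            0.0,
            self.f,
            -1.0 / self.f,
            0.0,
            L=self.focus_to_focus_length,
            aperture_diameter=self.back_aperture,
            label=self.label,
        )


#: Olympus 60x/1.2W objective used by the CLSM fixtures (f = 180/60 mm).
OLYMPUS_UISUPLAPO60XW = ObjectiveModel(
    f=180.0 / 60.0,
    na=1.2,
    focus_to_focus_length=40.0,
    back_aperture=7.0,
    working_distance=0.28,
    magnification=60.0,
    field_number=22.0,
    label="UISUPLAPO60XW Objective",
)


def system_2f(f: float, diameter: float = math.inf, label: str = "") -> list[TransferMatrix]:
    """Focus-to-focus propagation through a single lens: Space(f) + Lens(f)
    + Space(f)."""
    return [
        make_space(f),
        make_thin_lens(f, diameter=diameter, label=label),
        make_space(f),
    ]


def system_4f(
    f1: float,
    f2: float,
    diameter1: float = math.inf,
    diameter2: float = math.inf,
    label: str = "",
) -> list[TransferMatrix]:
    """A 4f relay: Space(f1) + Lens(f1) + Space(f1+f2) + Lens(f2) +
    Space(f2), imaging focus-to-focus with magnification -f2/f1."""
    tag = label or "4f"
    return [
        make_space(f1),
        make_thin_lens(f1, diameter=diameter1, label=f"{tag} lens 1"),
        make_space(f1 + f2),
        make_thin_lens(f2, diameter=diameter2, label=f"{tag} lens 2"),
        make_space(f2),
    ]


# ---------------------------------------------------------------------------
# CLSM detection path and pinhole study


def build_clsm_detection_path(defocus: float = 0.0) -> ImagingPath:
    """CLSM detection path from the focal spot to the pinhole plane.

    ``defocus`` (mm) displaces the focal spot from the objective's focal
    plane (positive moves the spot away from the objective).  The chain is
    an f=5 objective lens, a f=100 relay lens, then 4f(100, 75) and
    4f(40, 50) relays, ending exactly at the pinhole plane.
    """
    path = ImagingPath(label="CLSM detection")
    path.append(make_space(5.0 + defocus))
    path.append(make_thin_lens(5.0, label="Objective lens"))
    path.append(make_space(105.0))
    path.append(make_thin_lens(100.0, label="Relay lens"))
    path.append(make_space(100.0))
    path.append(system_4f(100.0, 75.0, label="4f-1"))
    path.append(system_4f(40.0, 50.0, label="4f-2"))
    return path


def clsm_detection_magnification() -> float:
    """Transverse magnification at the pinhole plane (the last conjugate of
    the focal spot): product of the stage magnifications -20, -0.75, -1.25
    = -18.75."""
    planes = intermediate_conjugates(build_clsm_detection_path())
    if not planes:
        raise RuntimeError("CLSM detection path has no conjugate planes")
    return planes[-1].magnification


def optimal_pinhole_diameter(focal_radius: float = CLSM_FOCAL_RADIUS_MM) -> float:
    """Pinhole diameter (mm) that exactly fits the image of the focal spot:
    |magnification| times the spot diameter."""
    return abs(clsm_detection_magnification()) * (2.0 * focal_radius)


#: Defocus sweep of the pinhole study, in mm (+-1000 nm around focus).
DEFAULT_DEFOCUS_POSITIONS_MM = tuple(
    z * 1e-6
    for z in (1000, 800, 500, 300, 150, 100, 50, 25, 0,
              -25, -50, -100, -150, -300, -500, -800, -1000)
)


def transmission_vs_defocus(
    pinhole_factor: float,
    positions: tuple[float, ...] = DEFAULT_DEFOCUS_POSITIONS_MM,
    n_rays: int = 100_000,
    seed: int | None = None,
    theta_max: float = math.pi / 2,
    focal_radius: float = CLSM_FOCAL_RADIUS_MM,
) -> np.ndarray:
    """Pinhole transmission efficiency versus focal-spot defocus.

    For each defocus the detection path is rebuilt, a pinhole of
    ``pinhole_factor`` times the optimal diameter is appended, and a
    seeded uniform ensemble emitted from the (displaced) focal spot is
    traced; the efficiency is the transmitted fraction.  The same input
    ensemble is reused across positions, as in a physical sweep of one
    specimen.
    """
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    pinhole = pinhole_factor * optimal_pinhole_diameter(focal_radius)
    rays = random_uniform_rays(
        -focal_radius, focal_radius, -theta_max, theta_max, n_rays, seed=seed
    )
    efficiencies = []
    for defocus in positions:
        path = build_clsm_detection_path(defocus)
        path.append(make_aperture(pinhole, label="Pinhole"))
        _, _, blocked, _, _, _ = trace_arrays(path, rays.ys, rays.thetas)
        efficiencies.append(float(np.count_nonzero(~blocked)) / n_rays)
    return np.asarray(efficiencies)


# ---------------------------------------------------------------------------
# CLSM scan relay


def build_scan_path() -> ImagingPath:
    """Scan relay from the polygonal mirror plane (object) to the sample.

    Two 4f relays (40/75 then 100/100, all 24.5 mm diameter) image the
    scan mirror onto the objective's back aperture; the objective then
    converts scan angle into focal-spot position at the sample.
    """
    path = ImagingPath(label="CLSM scan relay")
    path.append(system_4f(40.0, 75.0, diameter1=24.5, diameter2=24.5, label="scan 4f-1"))
    path.append(system_4f(100.0, 100.0, diameter1=24.5, diameter2=24.5, label="scan 4f-2"))
    path.append(make_space(180.0 / 40.0))
    path.append(OLYMPUS_UISUPLAPO60XW.as_matrix())
    path.append(make_space(180.0 / 40.0))
    return path


def scan_positions(angles: np.ndarray) -> np.ndarray:
    """Focal-spot heights (mm) at the sample for scan angles (rad) at the
    polygon plane; linear in the angle with zero crossing at zero."""
    angles = np.asarray(angles, dtype=float)
    path = build_scan_path()
    ys, _, blocked, _, _, _ = trace_arrays(
        path, np.zeros_like(angles), angles
    )
    if blocked.any():
        raise RuntimeError("scan fan clipped inside the relay")
    return ys


# ---------------------------------------------------------------------------
# Koehler illumination


#: axial position of the specimen plane in the Koehler train (mm): one
#: condenser focal length past the condenser.
KOHLER_SAMPLE_Z = 120.0


def build_kohler_path() -> ImagingPath:
    """Koehler illumination train from the lamp (object plane) to the eye.

    Collector f=10 with a 2 mm field diaphragm, then condenser, objective,
    tube and eyepiece lenses (all f=30, 25.4 mm) and a f=2 eye lens.
    """
    path = ImagingPath(label="Koehler illumination", object_height=0.1)
    path.append(make_space(20.0))
    path.append(make_thin_lens(10.0, diameter=25.4, label="Collector"))
    path.append(make_space(30.0))
    path.append(make_aperture(2.0, label="Field diaphragm"))
    path.append(make_space(10.0 + 30.0))
    path.append(make_thin_lens(30.0, diameter=25.4, label="Condenser"))
    path.append(make_space(30.0 + 30.0))
    path.append(make_thin_lens(30.0, diameter=25.4, label="Objective"))
    path.append(make_space(30.0 + 30.0))
    path.append(make_thin_lens(30.0, diameter=25.4, label="Tube"))
    path.append(make_space(30.0 + 30.0))
    path.append(make_thin_lens(30.0, diameter=25.4, label="Eyepiece"))
    path.append(make_space(30.0 + 2.0))
    path.append(make_thin_lens(2.0, diameter=10.0, label="Eye Entrance"))
    path.append(make_space(2.0))
    return path


def _subpath_from(path: ImagingPath, z0: float) -> ImagingPath:
    """The portion of ``path`` downstream of ``z0``; a free-space segment
    containing z0 is split there."""
    sub = ImagingPath(object_index=path.object_index, label=f"{path.label} (from z={z0:g})")
    z = 0.0
    for el in path.elements:
        z_next = z + el.L
        if z_next <= z0 + 1e-12:
            z = z_next
            continue
        if z < z0 - 1e-12:
            # z0 falls inside this element; only pure spaces can be split
            if el.C != 0.0 or el.A != 1.0 or el.has_finite_aperture:
                raise ValueError(f"cannot split element spanning z = {z0}")
            sub.append(make_space(z_next - z0, n=el.n_front, label=el.label))
        else:
            sub.append(el)
        z = z_next
    return sub


def kohler_conjugates() -> tuple[list[float], list[float]]:
    """Axial positions conjugate to the lamp and to the specimen plane.

    Both are computed with interior (mid-space) image solving; sample
    conjugates are reported in the full path's coordinates.  Koehler's
    defining property is that the two sets are disjoint.
    """
    path = build_kohler_path()
    source = [p.z for p in intermediate_conjugates(path, interior=True)]
    sub = _subpath_from(path, KOHLER_SAMPLE_Z)
    sample = [
        KOHLER_SAMPLE_Z + p.z for p in intermediate_conjugates(sub, interior=True)
    ]
    return source, sample


# ---------------------------------------------------------------------------
# widefield 4f imaging with a camera


def build_widefield_path(d1: float, d2: float, label: str = "") -> ImagingPath:
    """Widefield imaging: 4f(50, 50) with lens diameters ``d1``/``d2`` and
    a 10 mm camera aperture at the image plane."""
    path = ImagingPath(label=label or "Widefield 4f", object_height=10.0)
    path.append(system_4f(50.0, 50.0, diameter1=d1, diameter2=d2, label="widefield"))
    path.append(make_aperture(10.0, label="Camera"))
    return path


#: Lens diameters (d1, d2) realizing the three stop-placement scenarios:
#: equal undersized lenses (AS at lens 1, FS at lens 2, vignetting), a
#: larger first lens (AS at lens 2, FS at camera, no vignetting), and a
#: larger second lens (AS at lens 1, FS at camera, no vignetting, highest
#: throughput).
WIDEFIELD_SCENARIOS: dict[str, tuple[float, float]] = {
    "equal": (10.0, 10.0),
    "first-larger": (30.0, 8.0),
    "second-larger": (9.0, 30.0),
}
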