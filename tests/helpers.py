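"""Shared test utilities: independent brute-force oracles and random
system generation.

The stop scanners here follow the literal textbook procedure — fire test
rays of growing angle (or growing chief-ray height) until one is blocked,
and name the blocking element — so they are independent of the library's
closed-form ratio solvers.
"""

from __future__ import annotations

import numpy as np

from paraxial import (
    AnalysisError,
    ImagingPath,
    Ray,
    aperture_stop,
    axial_ray,
    chief_ray,
    field_stop,
    make_aperture,
    make_space,
    make_thin_lens,
    principal_ray,
    trace,
)


def scan_aperture_stop(path: ImagingPath) -> tuple[int, float]:
    """Find the AS by scanning on-axis rays of increasing angle.

    Returns (blocking element index, limiting angle) bracketed by
    bisection to 1e-10 relative.
    """
    hi = 1e-6
    while not trace(path, Ray(0.0, hi)).blocked:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("no on-axis blocking found")
    lo = 0.0
    while hi - lo > 1e-10 * hi:
        mid = 0.5 * (lo + hi)
        if trace(path, Ray(0.0, mid)).blocked:
            hi = mid
        else:
            lo = mid
    record = trace(path, Ray(0.0, hi))
    assert record.blocked
    return record.blocked_index, lo


def scan_field_stop(path: ImagingPath) -> tuple[int, float]:
    """Find the FS by scanning chief rays of increasing origin height.

    Returns (blocking element index, limiting height).
    """
    hi = 1e-6
    while not trace(path, chief_ray(path, hi)).blocked:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("no chief-ray blocking found")
    lo = 0.0
    while hi - lo > 1e-10 * hi:
        mid = 0.5 * (lo + hi)
        if trace(path, chief_ray(path, mid)).blocked:
            hi = mid
        else:
            lo = mid
    record = trace(path, chief_ray(path, hi))
    assert record.blocked
    return record.blocked_index, lo


def _ratio_gap(ratios: list[float]) -> float:
    """Relative gap between the two largest limiting ratios."""
    ordered = sorted(ratios, reverse=True)
    if len(ordered) < 2 or ordered[0] == 0:
        return np.inf
    return (ordered[0] - ordered[1]) / ordered[0]


def random_system(rng: np.random.Generator, with_apertures: bool = True) -> ImagingPath:
    """A random lens/space chain, optionally with finite apertures.

    When apertures are requested the system is rejected (and redrawn)
    unless the stop solvers succeed and no two apertures are within 0.1%
    of equally limiting, so that scan-vs-closed-form comparisons are not
    decided by floating-point ties.
    """
    for _ in range(200):
        path = ImagingPath()
        path.append(make_space(float(rng.uniform(20.0, 80.0))))
        for _ in range(int(rng.integers(2, 5))):
            sign = -1.0 if rng.random() < 0.2 else 1.0
            diameter = float(rng.uniform(5.0, 40.0)) if with_apertures else np.inf
            path.append(make_thin_lens(sign * float(rng.uniform(30.0, 150.0)),
                                       diameter=diameter))
            path.append(make_space(float(rng.uniform(20.0, 120.0))))
        if with_apertures and rng.random() < 0.5:
            path.append(make_aperture(float(rng.uniform(5.0, 30.0))))
            path.append(make_space(float(rng.uniform(10.0, 50.0))))
        if not with_apertures:
            return path
        try:
            axial = axial_ray(path)
            principal = principal_ray(path)
            aperture_stop(path)
            field_stop(path)
        except AnalysisError:
            continue
        # reject near-ties among limiting ratios for both test rays
        axial_ratios, chief_ratios = [], []
        unit_chief = chief_ray(path, 1.0)
        for _, M, el in path.entrance_states():
            if not el.has_finite_aperture:
                continue
            half = el.aperture_diameter * 0.5
            axial_ratios.append(abs(M.B) / half)
            h = M.A + M.B * unit_chief.theta
            if abs(h) > 1e-9:
                chief_ratios.append(abs(h) / half)
        if _ratio_gap(axial_ratios) < 1e-3 or _ratio_gap(chief_ratios) < 1e-3:
            continue
        # keep the special rays finite and sane
        if not (np.isfinite(axial.theta) and np.isfinite(principal.theta)):
            continue
        return path
    raise RuntimeError("could not draw a valid random system")
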