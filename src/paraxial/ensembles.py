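"""Ray ensembles: deterministic fans, random distributions, batch tracing,
transmission efficiency and output intensity histograms.

An ensemble stores its rays as flat numpy arrays so that tracing 10^5-10^6
rays through a path is a handful of vectorized passes.  All rays carry
unit weight; the emission statistics live in the distribution, not in a
per-ray power.

Two random sources are provided:

* ``random_uniform_rays`` — y and theta drawn independently and uniformly
  on their ranges;
* ``random_lambertian_rays`` — theta density proportional to cos(theta) on
  [-theta_max, theta_max] (meridional 2D convention), sampled by the
  inverse CDF theta = arcsin((2u - 1) sin(theta_max)); y uniform.

Sampling is reproducible: the same seed and parameters yield bitwise
identical ensembles.  Passing ``seed=None`` selects fresh OS entropy for
the deliberately unseeded mode.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .matrices import Ray
from .path import ImagingPath

__all__ = [
    "RayEnsemble",
    "IntensityHistogram",
    "uniform_fan",
    "random_uniform_rays",
    "random_lambertian_rays",
    "trace_many_through",
    "transmission_efficiency",
    "intensity_histogram",
]


@dataclass
class RayEnsemble:
    """A set of rays with distribution metadata.

    ``blocked_at`` is NaN for unblocked rays; ``blocked_index`` is the
    index of the blocking element in the traced path, -1 when unblocked.
    """

    ys: np.ndarray
    thetas: np.ndarray
    z: float = 0.0
    blocked: np.ndarray = None  # type: ignore[assignment]
    blocked_at: np.ndarray = None  # type: ignore[assignment]
    blocked_index: np.ndarray = None  # type: ignore[assignment]
    distribution: str = "custom"
    y_range: tuple[float, float] | None = None
    theta_range: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.ys = np.asarray(self.ys, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        if self.ys.shape != self.thetas.shape or self.ys.ndim != 1:
            raise ValueError("ys and thetas must be 1-D arrays of equal length")
        n = self.ys.size
        if self.blocked is None:
            self.blocked = np.zeros(n, dtype=bool)
        if self.blocked_at is None:
            self.blocked_at = np.full(n, np.nan)
        if self.blocked_index is None:
            self.blocked_index = np.full(n, -1, dtype=np.int64)

    @property
    def count(self) -> int:
        return int(self.ys.size)

    def __len__(self) -> int:
        return self.count

    def __iter__(self) -> Iterator[Ray]:
        for i in range(self.count):
            ba = self.blocked_at[i]
            yield Ray(
                y=float(self.ys[i]),
                theta=float(self.thetas[i]),
                z=float(self.z),
                blocked=bool(self.blocked[i]),
                blocked_at=None if math.isnan(ba) else float(ba),
            )

    def subset(self, mask: np.ndarray) -> "RayEnsemble":
        return RayEnsemble(
            ys=self.ys[mask],
            thetas=self.thetas[mask],
            z=self.z,
            blocked=self.blocked[mask],
            blocked_at=self.blocked_at[mask],
            blocked_index=self.blocked_index[mask],
            distribution=self.distribution,
            y_range=self.y_range,
            theta_range=self.theta_range,
            seed=self.seed,
        )

    def to_csv(self, fileobj) -> None:
        """Write rays as CSV with columns y,theta,blockedAt (blank when
        unblocked)."""
        writer = csv.writer(fileobj)
        writer.writerow(["y", "theta", "blockedAt"])
        for i in range(self.count):
            ba = self.blocked_at[i]
            writer.writerow(
                [repr(float(self.ys[i])), repr(float(self.thetas[i])),
                 "" if math.isnan(ba) else repr(float(ba))]
            )

    def to_dict(self) -> dict:
        return {
            "distribution": self.distribution,
            "count": self.count,
            "z": self.z,
            "yRange": self.y_range,
            "thetaRange": self.theta_range,
            "seed": self.seed,
            "y": self.ys.tolist(),
            "theta": self.thetas.tolist(),
            "blockedAt": [
                None if math.isnan(v) else v for v in self.blocked_at.tolist()
            ],
        }


@dataclass(frozen=True)
class IntensityHistogram:
    """Ray counts per height bin (unit-weight radiometry)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    total: int


def _axis(vmax: float, count: int) -> np.ndarray:
    # a single-sample axis sits at vmax (so M=1, yMax=0 means "on axis")
    if count == 1:
        return np.array([vmax], dtype=float)
    return np.linspace(-vmax, vmax, count)


def uniform_fan(y_max: float, theta_max: float, m: int = 1, n: int = 1) -> RayEnsemble:
    """A regular M x N grid of rays on [-y_max, y_max] x [-theta_max,
    theta_max]; a single-sample axis collapses to its maximum value."""
    if m < 1 or n < 1:
        raise ValueError("grid counts must be >= 1")
    ys, thetas = np.meshgrid(_axis(y_max, m), _axis(theta_max, n), indexing="ij")
    return RayEnsemble(
        ys=ys.ravel(),
        thetas=thetas.ravel(),
        distribution="uniform-grid",
        y_range=(-abs(y_max), abs(y_max)),
        theta_range=(-abs(theta_max), abs(theta_max)),
    )


def random_uniform_rays(
    y_min: float,
    y_max: float,
    theta_min: float,
    theta_max: float,
    max_count: int,
    seed: int | None = None,
) -> RayEnsemble:
    """Independent uniform draws y ~ U[y_min, y_max], theta ~ U[theta_min,
    theta_max]."""
    if y_min > y_max or theta_min > theta_max:
        raise ValueError("ranges must be ordered (min <= max)")
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    rng = np.random.default_rng(seed)
    return RayEnsemble(
        ys=rng.uniform(y_min, y_max, max_count),
        thetas=rng.uniform(theta_min, theta_max, max_count),
        distribution="random-uniform",
        y_range=(y_min, y_max),
        theta_range=(theta_min, theta_max),
        seed=seed,
    )


def random_lambertian_rays(
    y_min: float,
    y_max: float,
    theta_max: float,
    max_count: int,
    seed: int | None = None,
) -> RayEnsemble:
    """Lambertian angular emission: density proportional to cos(theta) on
    [-theta_max, theta_max], y uniform on [y_min, y_max]."""
    if not 0 < theta_max <= math.pi / 2:
        raise ValueError("theta_max must be in (0, pi/2]")
    if y_min > y_max:
        raise ValueError("y range must be ordered")
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, max_count)
    thetas = np.arcsin((2.0 * u - 1.0) * math.sin(theta_max))
    return RayEnsemble(
        ys=rng.uniform(y_min, y_max, max_count),
        thetas=thetas,
        distribution="random-lambertian",
        y_range=(y_min, y_max),
        theta_range=(-theta_max, theta_max),
        seed=seed,
    )


def trace_arrays(
    path: ImagingPath, ys: np.ndarray, thetas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Vectorized trace of raw (y, theta) arrays from the object plane.

    Returns (ys_out, thetas_out, blocked, blocked_at, blocked_index,
    z_exit); blocked rays keep the frozen state of their blocking plane.
    """
    path._require_elements()
    ys = np.array(ys, dtype=float, copy=True)
    thetas = np.array(thetas, dtype=float, copy=True)
    n = ys.size
    blocked = np.zeros(n, dtype=bool)
    blocked_at = np.full(n, np.nan)
    blocked_index = np.full(n, -1, dtype=np.int64)
    z = 0.0
    for i, el in enumerate(path.elements):
        if el.has_finite_aperture:
            newly = ~blocked & (np.abs(ys) > el.aperture_diameter * 0.5)
            if newly.any():
                blocked_at[newly] = z
                blocked_index[newly] = i
                blocked[newly] = True
        live = ~blocked
        if live.any():
            y_live = ys[live]
            t_live = thetas[live]
            ys[live] = el.A * y_live + el.B * t_live
            thetas[live] = el.C * y_live + el.D * t_live
        z += el.L
    return ys, thetas, blocked, blocked_at, blocked_index, z


def trace_many_through(
    path: ImagingPath, ensemble: RayEnsemble
) -> tuple[RayEnsemble, RayEnsemble]:
    """Trace every ray; returns (transmitted output ensemble at the exit
    plane, blocked sub-ensemble frozen at its blocking planes)."""
    ys, thetas, blocked, blocked_at, blocked_index, z_exit = trace_arrays(
        path, ensemble.ys, ensemble.thetas
    )
    traced = RayEnsemble(
        ys=ys,
        thetas=thetas,
        z=z_exit,
        blocked=blocked,
        blocked_at=blocked_at,
        blocked_index=blocked_index,
        distribution=ensemble.distribution,
        y_range=ensemble.y_range,
        theta_range=ensemble.theta_range,
        seed=ensemble.seed,
    )
    return traced.subset(~blocked), traced.subset(blocked)


def transmission_efficiency(path: ImagingPath, ensemble: RayEnsemble) -> float:
    """Fraction of input rays reaching the exit plane unblocked."""
    if ensemble.count == 0:
        raise ValueError("transmission efficiency of an empty ensemble is undefined")
    _, _, blocked, _, _, _ = trace_arrays(path, ensemble.ys, ensemble.thetas)
    return float(np.count_nonzero(~blocked)) / ensemble.count


def intensity_histogram(ensemble: RayEnsemble, bins: int = 100) -> IntensityHistogram:
    """Histogram of ray heights into equal-width bins over the data range."""
    if ensemble.count == 0:
        raise ValueError("cannot histogram an empty ensemble")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, edges = np.histogram(ensemble.ys, bins=bins)
    return IntensityHistogram(bin_edges=edges, counts=counts, total=ensemble.count)
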