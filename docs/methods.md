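# Methods

## Model and conventions

The engine works entirely in the paraxial (small-angle) regime: rays are
(height, angle) pairs transformed linearly by 2×2 ray-transfer matrices,
and no trigonometric function is ever applied to a ray angle inside the
engine.  Conventions, chosen once and used everywhere:

- light travels toward +z; lengths in millimetres, angles in radians;
  configuration files carry no units (mm/rad implied);
- heights are positive above the axis; a radius of curvature is positive
  when its centre of curvature lies downstream of the surface;
- angles are *physical* angles (not reduced n·θ).  The refractive index
  therefore enters only through dielectric-interface matrices and through
  the n factor of the optical invariant, and the determinant of any
  element or composition is n_front/n_back (validated at construction to
  a scale-aware 1e−8; the test suite checks 1e−10 on random products).

Free space in a medium of index n is [[1, d], [0, 1]] under this
convention — the index affects only interface refraction — and
composition requires adjacent media to match, which catches
inconsistently assembled systems early.

## Apertures and blocking

Blocking is ray state, not a matrix operation.  An element with a finite
clear diameter D marks a ray blocked when it *arrives* at the element's
entrance plane with |y| > D/2; the edge itself transmits, so the axial
and principal rays — defined as grazing a stop edge — trace as
transmitted.  Once blocked, a ray's (y, θ) freeze at the blocking plane.
For thick elements (thick lenses, objective black boxes) the clear
aperture is checked at the entrance plane only; clipping inside the glass
is out of scope.

## Stops, special rays and invariants

The aperture stop is found from the on-axis test ray (0, 1): by
linearity its height at any plane is the B element of the object→plane
matrix, so the AS is the finite aperture maximizing |B|/(D/2).  The field
stop repeats the argument with the unit chief ray (height 1, angle chosen
so it crosses the AS centre).  These closed-form solvers replace the
literal procedure of scanning rays of growing angle/height until one is
blocked; the equivalence is not assumed but tested, against a
doubling-plus-bisection scanner, on hundreds of random systems.  Ties
between equally limiting apertures go to the smallest z (so in a
symmetric relay with equal lenses the *first* lens is named the AS).
Degenerate geometries — an AS conjugate to the object, or no aperture
limiting the chief ray — raise typed analysis errors rather than
returning unusable rays.  A finite object distance is required; objects
at infinity are not supported by the stop analysis.

The field of view is reported at the object plane (mm), the object-space
NA as n·sin θₐ with θₐ the axial-ray angle (the engine itself uses θₐ
directly).  The Lagrange invariant is evaluated at the object plane and
reported positive.

The two-ray decomposition solves r = a·principal + b·axial by Cramer's
rule on invariants: a = n(y θₐ − yₐ θ)/H, b = n(y_p θ − y θ_p)/H.  This
form reconstructs exactly and makes both coefficients manifestly
conserved along unblocked traces.  A blocked ray with max(|a|, |b|) > 1
(strict) was outside the design envelope and is counted an expected
loss; a blocked ray at or inside the boundary is vignetted, and the
element blocking the most vignetted rays is named in the report.

## Conjugate planes

`intermediate_conjugates` examines the cumulative matrix at element
boundaries and reports planes with |B| < 1e−9 mm (a tolerance sized for
floating-point products of exact conjugate distances).  With
`interior=True` it additionally solves B(s) = B₀ + s·D₀ = 0 inside pure
free-space segments, which is required for systems — the Köhler train is
the canonical case — whose images fall between elements.  The default
stays boundaries-only, which is what the pinhole-sizing workflow needs.

## Ray ensembles and Monte-Carlo choices

Ensembles are stored as flat numpy arrays and traced vectorially (one
pass per element), so 10⁵–10⁶ rays are cheap; the vectorized tracer is
cross-checked against the scalar per-ray engine in the tests, including
blocking positions.  Samplers:

- uniform grid fans (a single-sample axis collapses to its maximum, so
  `y_max=0, m=1` means "on axis");
- independent uniform draws in y and θ;
- Lambertian emission in the 2D meridional convention, density ∝ cos θ
  on [−θ_max, θ_max], by inverse CDF θ = arcsin((2u−1)·sin θ_max).

All randomness flows through `numpy.random.default_rng(seed)`: a given
seed reproduces ensembles bitwise; `seed=None` is the explicit unseeded
mode.  Histograms use equal-width bins over the observed range, 100 by
default; rays carry unit weight (no wavelength, polarization or cos⁴
radiometry).

## Fixtures and their parameters

- **CLSM detection** (focal spot → pinhole): f=5 objective lens, f=100
  relay, then 4f(100, 75) and 4f(40, 50).  The pinhole plane is the last
  conjugate of the spot, magnification (−20)(−0.75)(−1.25) = −18.75, so a
  0.5 µm focal spot (radius 0.000250 mm) needs a 9.375 µm pinhole.  The
  defocus study rebuilds the path with the spot displaced, appends a
  pinhole of ⅓×, 1× or 3× the optimal diameter, and traces one seeded
  uniform ensemble reused across all positions.  The emission half-angle
  defaults to π/2 (a full meridional half-circle): the focal spot of a
  high-NA objective radiates into the whole acceptance cone, and this is
  what gives the defocus curve its sensitivity.  Default sweep: ±1000 nm
  in 17 steps, 10⁵ rays (10⁴ in the tests and acceptance script, where
  binomial noise of ~0.005 is ample for the qualitative orderings).
- **CLSM scan relay** (polygon mirror → sample): 4f(40, 75) and
  4f(100, 100) relays (24.5 mm optics) into a 60×/1.2W objective modelled
  as a focal-plane-to-focal-plane box [[0, f], [−1/f, 0]] with f = 3 mm,
  physical length 40 mm, 7 mm back aperture.  The scan curve y(θ) is
  checked for linearity and zero crossing only: the absolute span quoted
  for this instrument is unit-ambiguous in the source material (the
  black-box model gives ≈698 µm over ±10°), so no magnitude is asserted.
- **Köhler illumination**: collector f=10 with a 2 mm field diaphragm,
  then condenser/objective/tube/eyepiece (f=30, 25.4 mm) and an f=2 eye
  lens, total length 304 mm; the specimen sits one condenser focal length
  past the condenser at z=120 mm.  The defining check is that source
  conjugates (z = 40, 160, 280 mm) and specimen conjugates (z = 240,
  304 mm) are disjoint, and that the source→specimen matrix has B far
  from zero: light from any single source point arrives spread over the
  field rather than focused — with these printed distances the bundle is
  spread and decollimated (D = 2/3), not strictly parallel, so the test
  asserts the conjugate separation, which is the property that matters
  for uniformity.
- **Widefield 4f + camera**: 4f(50, 50) with a 10 mm camera at the image
  plane and object half-height 5 mm.  The lens diameters for the three
  stop-placement scenarios are (10, 10), (30, 8) and (9, 30).  The
  asymmetric pairs were *derived*, not tuned: with a 10 mm camera and
  5 mm object half-height, a vignetting-free layout needs the larger lens
  to be at least 20 mm plus the smaller diameter (so the corner of the
  (a, b) envelope clears it), and the transmitted fraction scales with
  the smaller diameter, so 9 > 8 makes the well-placed-AS scenario
  strictly brighter (ratio 9:8 ≈ 1.12 at 10⁵ rays).

## What the synthetic ensembles do and do not show

The Monte-Carlo sources emulate geometric emission only: uniform or
cosine-weighted angular fans of unit-weight meridional rays.  Passing
tests therefore demonstrate the *geometric* throughput and vignetting
behaviour of a design — they say nothing about diffraction (the true
confocal axial response), aberrations, skew rays, polarization or source
spectra, none of which exist in a paraxial meridional model.  Defocus
curves in particular are geometric-optics sectioning curves, sharper than
a diffraction calculation would give.

## Numerical choices

- imaging tolerance |B| < 1e−9 mm; stop-ratio ties broken by a 1e−12
  absolute window toward smaller z; chief-ray heights below 1e−9 at an
  aperture mark it non-limiting in the FS search;
- afocal systems (C = 0) report infinite focal quantities instead of
  raising; `gauss_image_solve` reports an object at the focal plane as
  imaging to infinity;
- Gaussian q follows the same physical-angle convention as the matrices;
  the index enters through interfaces and through w-recovery,
  1/q = 1/R − iλ/(π n w²).

## Known limitations

Meridional 2D rays only (no skew rays), no tilted/decentred elements, no
curved mirrors in folded geometries (use unfolded equivalent lenses), no
wavelength-dependent indices, no aperture clipping of Gaussian beams, no
built-in optimization.  Pupil/window positions and telecentricity metrics
are derivable from the primitives but not provided.
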