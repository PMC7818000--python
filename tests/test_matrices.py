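"""Unit and property tests for rays, element matrices and closed-form
system properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paraxial import (
    Ray,
    TransferMatrix,
    compose,
    gauss_image_solve,
    make_aperture,
    make_dielectric_interface,
    make_space,
    make_thick_lens,
    make_thin_lens,
    optical_invariant,
    system_properties,
    transform,
)


def abcd(M):
    return (M.A, M.B, M.C, M.D)


class TestConstructors:
    @pytest.mark.parametrize(
        "M, expected",
        [
            (make_space(50.0), (1, 50, 0, 1)),
            (make_space(0.0), (1, 0, 0, 1)),
            (make_space(10.0, n=1.5), (1, 10, 0, 1)),
            (make_thin_lens(50.0), (1, 0, -0.02, 1)),
            (make_thin_lens(-100.0), (1, 0, 0.01, 1)),
            (make_dielectric_interface(math.inf, 1.0, 1.5), (1, 0, 0, 2 / 3)),
            (make_dielectric_interface(50.0, 1.0, 1.5), (1, 0, -1 / 150, 2 / 3)),
            (make_dielectric_interface(-50.0, 1.5, 1.0), (1, 0, -0.01, 1.5)),
            (make_aperture(10.0), (1, 0, 0, 1)),
        ],
    )
    def test_element_matrices(self, M, expected):
        assert abcd(M) == pytest.approx(expected, abs=1e-12)

    def test_space_in_glass_keeps_unit_determinant(self):
        # physical angles: the index only enters through interfaces
        M = make_space(10.0, n=1.5)
        assert M.n_front == M.n_back == 1.5
        assert M.determinant == pytest.approx(1.0, abs=1e-12)

    def test_interface_determinant_is_index_ratio(self):
        M = make_dielectric_interface(50.0, 1.0, 1.5)
        assert M.determinant == pytest.approx(2 / 3, abs=1e-12)

    def test_thick_lens_equals_three_factor_product(self):
        M = make_thick_lens(1.5, 50.0, -50.0, 10.0)
        oracle = compose([
            make_dielectric_interface(50.0, 1.0, 1.5),
            make_space(10.0, n=1.5),
            make_dielectric_interface(-50.0, 1.5, 1.0),
        ])
        assert abcd(M) == pytest.approx(abcd(oracle), abs=1e-15)
        assert abcd(M) == pytest.approx(
            (0.93333333, 6.66666667, -0.01933333, 0.93333333), abs=1e-7
        )
        assert M.L == 10.0

    def test_thick_lens_efl_matches_lensmaker(self):
        M = make_thick_lens(1.5, 50.0, -50.0, 10.0)
        assert -1.0 / M.C == pytest.approx(51.724, abs=1e-3)

    def test_flat_thick_slab_is_identity(self):
        M = make_thick_lens(1.5, math.inf, math.inf, 0.0)
        assert abcd(M) == pytest.approx((1, 0, 0, 1), abs=1e-15)

    @pytest.mark.parametrize(
        "build",
        [
            lambda: make_space(-1.0),
            lambda: make_thin_lens(0.0),
            lambda: make_dielectric_interface(0.0, 1.0, 1.5),
            lambda: make_aperture(0.0),
            lambda: make_aperture(-2.0),
            lambda: TransferMatrix(1, 0, 0, 1, aperture_diameter=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, build):
        with pytest.raises(ValueError):
            build()

    def test_spherical_interface_matches_exact_snell_at_small_angle(self):
        """Paraxial interface matrix vs an exact vector-Snell refraction."""

        def exact_refraction(R, n1, n2, y, theta):
            # intersect the ray (from the vertex plane) with the sphere of
            # radius R centred at (z=R, y=0), then apply vector Snell
            d = np.array([math.cos(theta), math.sin(theta)])
            p0 = np.array([0.0, y])
            c = np.array([R, 0.0])
            oc = p0 - c
            b = 2.0 * d.dot(oc)
            disc = b * b - 4.0 * (oc.dot(oc) - R * R)
            roots = sorted([(-b - math.sqrt(disc)) / 2.0, (-b + math.sqrt(disc)) / 2.0],
                           key=abs)
            p = p0 + roots[0] * d
            n_vec = (p - c) / R
            if n_vec.dot(d) > 0:
                n_vec = -n_vec
            mu = n1 / n2
            cos_i = -d.dot(n_vec)
            t = mu * d + (mu * cos_i - math.sqrt(1 - mu * mu * (1 - cos_i**2))) * n_vec
            return p[1], math.atan2(t[1], t[0])

        for R, n1, n2 in [(50.0, 1.0, 1.5), (-50.0, 1.5, 1.0), (80.0, 1.0, 1.33)]:
            M = make_dielectric_interface(R, n1, n2)
            y, theta = 1e-4 * abs(R), 1e-4
            y_exact, theta_exact = exact_refraction(R, n1, n2, y, theta)
            theta_matrix = M.C * y_exact + M.D * theta
            assert theta_matrix == pytest.approx(theta_exact, abs=1e-10)


class TestComposeAndTransform:
    def test_4f_relay_is_minus_identity(self):
        relay = compose([
            make_space(50.0), make_thin_lens(50.0), make_space(100.0),
            make_thin_lens(50.0), make_space(50.0),
        ])
        assert abcd(relay) == pytest.approx((-1, 0, 0, -1), abs=1e-12)
        assert relay.L == 200.0

    def test_spaces_compose_additively(self):
        assert abcd(compose([make_space(30.0), make_space(20.0)])) == abcd(
            make_space(50.0)
        )

    def test_single_element_composition_is_identity_operation(self):
        M = make_thin_lens(75.0)
        assert abcd(compose([M])) == abcd(M)

    def test_index_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compose([make_space(10.0, n=1.5), make_space(10.0, n=1.0)])

    @pytest.mark.parametrize(
        "M, ray_in, ray_out",
        [
            (make_space(50.0), (0.0, 0.1), (5.0, 0.1)),
            (make_thin_lens(50.0), (1.0, 0.0), (1.0, -0.02)),
            (make_thin_lens(50.0), (2.0, 0.0), (2.0, -0.04)),
        ],
    )
    def test_transform_examples(self, M, ray_in, ray_out):
        out = transform(M, Ray(*ray_in))
        assert (out.y, out.theta) == pytest.approx(ray_out, abs=1e-12)
        assert out.z == M.L

    def test_transform_through_composed_relay(self):
        relay = compose([
            make_space(50.0), make_thin_lens(50.0), make_space(100.0),
            make_thin_lens(50.0), make_space(50.0),
        ])
        out = transform(relay, Ray(2.0, 0.1))
        assert (out.y, out.theta) == pytest.approx((-2.0, -0.1), abs=1e-12)

    @pytest.mark.parametrize(
        "y, expect_blocked",
        [(4.9, False), (5.1, True), (-5.0, False), (5.0, False)],
    )
    def test_aperture_blocking_is_edge_inclusive(self, y, expect_blocked):
        out = transform(make_aperture(10.0), Ray(y, 0.3, z=7.0))
        assert out.blocked is expect_blocked
        if expect_blocked:
            assert out.blocked_at == 7.0
            assert (out.y, out.theta) == (y, 0.3)

    def test_blocked_ray_passes_unchanged(self):
        blocked = Ray(9.0, 0.2, z=5.0, blocked=True, blocked_at=5.0)
        assert transform(make_thin_lens(50.0), blocked) is blocked


class TestSystemProperties:
    def test_thin_lens_principal_planes_at_element(self):
        props = system_properties(make_thin_lens(50.0))
        assert props.efl_back == pytest.approx(50.0)
        assert props.efl_front == pytest.approx(50.0)
        assert props.principal_plane_front == 0.0
        assert props.principal_plane_back == 0.0

    def test_thick_lens_principal_plane_inside_vertex(self):
        props = system_properties(make_thick_lens(1.5, 50.0, -50.0, 10.0))
        assert props.principal_plane_back == pytest.approx(-3.448, abs=1e-3)
        assert props.principal_plane_front == pytest.approx(-3.448, abs=1e-3)

    def test_4f_relay_imaging_with_unit_negative_magnification(self):
        relay = compose([
            make_space(50.0), make_thin_lens(50.0), make_space(100.0),
            make_thin_lens(50.0), make_space(50.0),
        ])
        props = system_properties(relay)
        assert props.is_imaging
        assert props.transverse_magnification == pytest.approx(-1.0)
        assert props.angular_magnification == pytest.approx(-1.0)

    def test_afocal_system_reports_infinities(self):
        props = system_properties(make_space(100.0))
        assert math.isinf(props.efl_back)
        assert math.isinf(props.principal_plane_front)
        assert not props.is_imaging


class TestOpticalInvariant:
    def test_arithmetic_example(self):
        assert optical_invariant(1.0, Ray(1.0, 0.1), Ray(0.0, 0.05)) == pytest.approx(
            0.05
        )

    def test_preserved_by_relay(self):
        relay = compose([
            make_space(50.0), make_thin_lens(50.0), make_space(100.0),
            make_thin_lens(50.0), make_space(50.0),
        ])
        r1, r2 = transform(relay, Ray(1.0, 0.1)), transform(relay, Ray(0.0, 0.05))
        assert optical_invariant(1.0, r1, r2) == pytest.approx(0.05, rel=1e-12)

    def test_self_invariant_is_zero(self):
        r = Ray(1.3, -0.07)
        assert optical_invariant(1.0, r, r) == 0.0

    def test_rays_at_different_z_rejected(self):
        with pytest.raises(ValueError, match="same z"):
            optical_invariant(1.0, Ray(1.0, 0.1, z=0.0), Ray(0.0, 0.05, z=10.0))


class TestGaussImaging:
    @pytest.mark.parametrize(
        "f, do, di, m",
        [(50.0, 100.0, 100.0, -1.0), (50.0, 75.0, 150.0, -2.0),
         (50.0, 25.0, -50.0, 2.0)],
    )
    def test_conjugate_examples(self, f, do, di, m):
        got_di, got_m = gauss_image_solve(f, do)
        assert got_di == pytest.approx(di, rel=1e-12)
        assert got_m == pytest.approx(m, rel=1e-12)
        # the solved distance really is the B = 0 plane
        M = compose([make_space(do), make_thin_lens(f), make_space(abs(di))])
        if di > 0:
            assert abs(M.B) < 1e-9
            assert M.A == pytest.approx(m, rel=1e-12)

    def test_object_at_focus_images_to_infinity(self):
        di, m = gauss_image_solve(50.0, 50.0)
        assert math.isinf(di) and math.isinf(m)


# ---------------------------------------------------------------------------
# property-based invariants

signed_f = st.one_of(st.floats(20.0, 300.0), st.floats(-300.0, -20.0))


@given(
    d=st.floats(0.0, 500.0),
    f=signed_f,
    R1=st.one_of(st.floats(20.0, 500.0), st.floats(-500.0, -20.0)),
    n=st.floats(1.0, 2.0),
    t=st.floats(0.0, 30.0),
)
def test_determinant_identity_for_constructors(d, f, R1, n, t):
    for M in (
        make_space(d, n=n),
        make_thin_lens(f),
        make_dielectric_interface(R1, 1.0, n),
        make_thick_lens(n, R1, -R1, t),
    ):
        assert M.determinant == pytest.approx(M.n_front / M.n_back, abs=1e-10)


@given(
    f=signed_f,
    d1=st.floats(1.0, 200.0),
    d2=st.floats(1.0, 200.0),
    y=st.floats(-10.0, 10.0),
    theta=st.floats(-0.5, 0.5),
    a=st.floats(-3.0, 3.0),
    b=st.floats(-3.0, 3.0),
)
def test_transform_is_linear(f, d1, d2, y, theta, a, b):
    M = compose([make_space(d1), make_thin_lens(f), make_space(d2)])
    r1, r2 = Ray(y, theta), Ray(theta, -y / 7.0)
    mixed = transform(M, Ray(a * r1.y + b * r2.y, a * r1.theta + b * r2.theta))
    o1, o2 = transform(M, r1), transform(M, r2)
    assert mixed.y == pytest.approx(a * o1.y + b * o2.y, abs=1e-9)
    assert mixed.theta == pytest.approx(a * o1.theta + b * o2.theta, abs=1e-9)


@given(
    n=st.floats(1.3, 1.9),
    R1=st.one_of(st.floats(25.0, 400.0), st.floats(-400.0, -25.0)),
    R2=st.one_of(st.floats(25.0, 400.0), st.floats(-400.0, -25.0)),
    t=st.floats(0.5, 25.0),
)
def test_thick_lens_matches_lensmaker_closed_form(n, R1, R2, t):
    M = make_thick_lens(n, R1, R2, t)
    inv_f = (n - 1.0) * (1.0 / R1 - 1.0 / R2 + (n - 1.0) * t / (n * R1 * R2))
    assert -M.C == pytest.approx(inv_f, rel=1e-9, abs=1e-12)


@given(f=signed_f, do=st.floats(5.0, 500.0))
def test_gauss_solution_satisfies_gauss_law(f, do):
    di, _ = gauss_image_solve(f, do)
    if math.isinf(di):
        return
    assert 1.0 / do + 1.0 / di == pytest.approx(1.0 / f, rel=1e-9)


def test_compose_equals_sequential_transform(rng):
    """Applying a composed matrix equals element-by-element transformation."""
    for _ in range(200):
        elements = [make_space(rng.uniform(0.0, 100.0))]
        for _ in range(rng.integers(1, 5)):
            elements.append(make_thin_lens(rng.choice([-1, 1]) * rng.uniform(20, 200)))
            elements.append(make_space(rng.uniform(0.0, 100.0)))
        M = compose(elements)
        for _ in range(5):
            ray = Ray(rng.uniform(-10, 10), rng.uniform(-0.3, 0.3))
            step = ray
            for el in elements:
                step = transform(el, step)
            direct = transform(M, ray)
            assert direct.y == pytest.approx(step.y, rel=1e-9, abs=1e-9)
            assert direct.theta == pytest.approx(step.theta, rel=1e-9, abs=1e-9)
            assert direct.z == pytest.approx(step.z, abs=1e-9)
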