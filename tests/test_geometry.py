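"""Differential-geometry checks against symbolic and closed-form oracles."""

import math

import numpy as np
import pytest
import sympy as sp

from ulcersim import geometry
from ulcersim.errors import InvalidSpecError, RegularityError
from ulcersim.geometry import PatchSpec, SubDomain


def symbolic_forms(xe, ye, ze, u, v):
    """Independent oracle: fundamental forms and Gaussian curvature by
    symbolic differentiation of the given chart."""
    X = sp.Matrix([xe, ye, ze])
    Xu, Xv = X.diff(u), X.diff(v)
    E, F, G = Xu.dot(Xu), Xu.dot(Xv), Xv.dot(Xv)
    n = Xu.cross(Xv)
    nhat = n / sp.sqrt(n.dot(n))
    e = X.diff(u, 2).dot(nhat)
    f = X.diff(u, 1, v, 1).dot(nhat)
    g = X.diff(v, 2).dot(nhat)
    k = (e * g - f**2) / (E * G - F**2)
    return sp.lambdify((u, v), [E, F, G, e, f, g, k], "numpy")


U, V = sp.symbols("u v", real=True)

SURFACE_CASES = [
    (
        "plane",
        geometry.make_plane(),
        (U, V, sp.Integer(0)),
        [(0.3, 0.7), (0.1, 0.9)],
    ),
    (
        "sphere-R2",
        geometry.make_sphere(2.0),
        (2 * sp.sin(V) * sp.cos(U), 2 * sp.sin(V) * sp.sin(U), 2 * sp.cos(V)),
        [(0.5, 1.0), (2.0, 2.2)],
    ),
    (
        "circular-catenoid",
        geometry.make_elliptic_catenoid(
            PatchSpec(a=1, b=1, c=1, u_range=(0.0, 2 * math.pi), v_range=(0.0, 1.0))
        ),
        (sp.cosh(V) * sp.cos(U), sp.cosh(V) * sp.sin(U), V),
        [(0.0, 0.0), (1.2, 0.4), (4.0, 0.9)],
    ),
    (
        "elliptic-catenoid",
        geometry.make_elliptic_catenoid(
            PatchSpec(a=0.06, b=0.03, c=1.5, v_range=(0.0, 0.1))
        ),
        (
            sp.Rational(6, 100) * sp.cosh(V / sp.Rational(3, 2)) * sp.cos(U),
            sp.Rational(3, 100) * sp.cosh(V / sp.Rational(3, 2)) * sp.sin(U),
            V,
        ),
        [(0.4, 0.02), (2.5, 0.08)],
    ),
]


@pytest.mark.parametrize("name,surf,chart,points", SURFACE_CASES, ids=[c[0] for c in SURFACE_CASES])
def test_forms_and_curvature_match_symbolic_oracle(name, surf, chart, points):
    """E, F, G, e, f, g and k agree with symbolic differentiation to 1e-8
    relative at interior sample points."""
    oracle = symbolic_forms(*chart, U, V)
    for (uu, vv) in points:
        ff = geometry.fundamental_forms(surf, uu, vv)
        k = geometry.gaussian_curvature(surf, uu, vv)
        expected = oracle(uu, vv)
        got = [ff.E, ff.F, ff.G, ff.e, ff.f, ff.g, k]
        for val, exp in zip(got, expected):
            assert val == pytest.approx(exp, rel=1e-8, abs=1e-10)


def test_known_curvatures():
    """Plane k=0, sphere k=1/R^2, circular catenoid k=-1/(c^2 cosh^4(v/c))."""
    plane = geometry.make_plane()
    assert geometry.gaussian_curvature(plane, 0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    sphere = geometry.make_sphere(2.0)
    uu = np.linspace(0.2, 5.0, 7)
    vv = np.linspace(0.3, 2.8, 7)
    k = geometry.gaussian_curvature(sphere, uu, vv)
    assert np.allclose(k, 0.25, rtol=1e-10)

    cat = geometry.make_elliptic_catenoid(
        PatchSpec(a=1, b=1, c=1, u_range=(0, 2 * math.pi), v_range=(0, 1))
    )
    for vv in (0.0, 0.35, 0.9):
        k = geometry.gaussian_curvature(cat, 0.7, vv)
        assert k == pytest.approx(-1.0 / math.cosh(vv) ** 4, rel=1e-10)


def test_elliptic_catenoid_map_and_domain():
    spec = PatchSpec(a=1, b=1, c=1, v_range=(0.0, 0.34))
    surf = geometry.make_elliptic_catenoid(spec)
    assert surf.map(0.0, 0.0) == pytest.approx([1.0, 0.0, 0.0])
    xu, xv = surf.d1(0.0, 0.0)
    assert xv == pytest.approx([0.0, 0.0, 1.0])
    assert surf.domain == ((0.0, math.pi), (0.0, 0.34))


def test_catenoid_first_form_at_waist():
    """Circular catenoid a=b=c=1: at v=0 the metric is E=G=1, F=0."""
    surf = geometry.make_elliptic_catenoid(PatchSpec(a=1, b=1, c=1, v_range=(0, 1)))
    ff = geometry.fundamental_forms(surf, 0.0, 0.0)
    assert (ff.E, ff.F, ff.G) == pytest.approx((1.0, 0.0, 1.0), abs=1e-12)


def test_invalid_patch_spec_rejected():
    with pytest.raises(InvalidSpecError):
        PatchSpec(a=-1.0, b=1.0, c=1.0)
    with pytest.raises(InvalidSpecError):
        PatchSpec(a=1.0, b=1.0, c=1.0, v_range=(0.0, 0.0))


def test_degenerate_normal_raises_regularity_error():
    bad = geometry.surface_from_map(
        lambda u, v: np.stack([u, u, np.zeros_like(u)], axis=-1),
        domain=((0.0, 1.0), (0.0, 1.0)),
    )
    with pytest.raises(RegularityError):
        geometry.fundamental_forms(bad, 0.5, 0.5)


def test_surface_area_plane_and_hemisphere():
    plane = geometry.make_plane()
    assert geometry.surface_area(plane) == pytest.approx(1.0, rel=1e-12)

    for R in (1.0, 1.7):
        hemi = geometry.make_sphere(R, v_range=(0.0, math.pi / 2))
        assert geometry.surface_area(hemi, tol=1e-10) == pytest.approx(
            2 * math.pi * R**2, rel=1e-8
        )


def test_area_quadrature_tolerance_consistency():
    """Refining the tolerance changes the catenoid area by less than the
    looser tolerance itself."""
    surf = geometry.make_elliptic_catenoid(PatchSpec(a=0.06, b=0.03, c=0.4, v_range=(0, 0.1)))
    a_loose = geometry.surface_area(surf, tol=1e-6)
    a_tight = geometry.surface_area(surf, tol=1e-12)
    assert abs(a_loose - a_tight) / a_tight < 1e-6


def test_region_outside_domain_rejected():
    surf = geometry.make_plane()
    with pytest.raises(InvalidSpecError):
        geometry.surface_area(surf, SubDomain.rect(0.0, 2.0, 0.0, 1.0))


def test_angle_excess_plane_triangle_is_zero():
    plane = geometry.make_plane()
    tri = SubDomain.triangle((0.1, 0.1), (0.8, 0.2), (0.3, 0.9))
    assert geometry.angle_excess(plane, tri) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("R", [1.0, 2.5])
def test_gauss_bonnet_sphere_octant(R):
    """A sphere octant is a geodesic triangle with three right angles:
    angle excess pi/2, independent of radius, to 1e-6."""
    sphere = geometry.make_sphere(R, u_range=(0.0, math.pi / 2), v_range=(0.0, math.pi / 2))
    excess = geometry.angle_excess(sphere, sphere.full_region(), tol=1e-10)
    assert excess == pytest.approx(math.pi / 2, abs=1e-6)


def test_angle_excess_small_triangle_matches_local_curvature():
    """On a slowly varying surface, excess ~ k(centroid) * area within 1%."""
    sphere = geometry.make_sphere(3.0)
    tri = SubDomain.triangle((1.0, 1.2), (1.06, 1.2), (1.0, 1.26))
    excess = geometry.angle_excess(sphere, tri, tol=1e-12)
    centroid = tri.vertices.mean(axis=0)
    k = geometry.gaussian_curvature(sphere, *centroid)
    area = geometry.surface_area(sphere, tri, tol=1e-12)
    assert excess == pytest.approx(k * area, rel=1e-2)


def test_curvature_supremum_plane_and_sphere():
    plane = geometry.make_plane()
    assert geometry.curvature_supremum(plane).value == pytest.approx(0.0, abs=1e-12)
    R = 2.0
    sphere = geometry.make_sphere(R, v_range=(0.5, 2.5))
    sup = geometry.curvature_supremum(sphere, grid=(50, 50))
    assert sup.value == pytest.approx(1 / R**2, rel=1e-10)


def test_curvature_supremum_refines_interior_peak():
    """Local refinement localizes an interior maximum of a closed-form
    field well beyond the coarse grid spacing."""
    k = lambda u, v: np.exp(-((u - 0.37) ** 2 + (v - 0.61) ** 2) / 0.01)
    sup = geometry.curvature_supremum(k, SubDomain.rect(0, 1, 0, 1), grid=(40, 40))
    assert sup.value == pytest.approx(1.0, rel=1e-6)
    assert (sup.u, sup.v) == pytest.approx((0.37, 0.61), abs=1e-3)


def test_plane_contact_full_and_tangent_sphere():
    plane = geometry.make_plane()
    contact = geometry.plane_contact_region(plane, 0.0, 1e-9, grid=(50, 50))
    assert contact.mask.all()
    assert contact.area == pytest.approx(1.0, rel=1e-9)

    # sphere resting tangent on z = -R: contact area -> 0 with tol
    sphere = geometry.make_sphere(1.0, v_range=(2.6, math.pi - 1e-3))
    contact = geometry.plane_contact_region(sphere, -1.0, 1e-6, grid=(200, 200))
    assert contact.area < 1e-4


def test_half_cylinder_contact_strip_matches_analytic():
    """Cylinder of radius r lying on z=0: tol_z = r(1-cos t) selects the
    strip |v| <= t of area 2 L r t.  Uses the finite-difference path."""
    r, L, theta = 0.5, 2.0, 0.3

    def cyl(u, v):
        return np.stack([u, r * np.sin(v), r * (1 - np.cos(v))], axis=-1)

    surf = geometry.surface_from_map(cyl, ((0.0, L), (-math.pi / 2, math.pi / 2)), name="half-cylinder")
    assert surf.derivative_mode == "finite-difference"
    tol_z = r * (1 - math.cos(theta))
    contact = geometry.plane_contact_region(surf, 0.0, tol_z, grid=(200, 400))
    assert contact.area == pytest.approx(2 * L * r * theta, rel=1e-2)


def test_patch_spec_text_round_trip():
    spec = PatchSpec(a=0.0572, b=0.02744, c=3.75, d=4.8e-4, v_range=(0.0, 0.092))
    text = geometry.patch_spec_to_text(spec)
    back = geometry.patch_spec_from_text(text)
    assert back == spec


def test_curvature_grid_frame_columns():
    surf = geometry.make_sphere(1.0, v_range=(0.5, 2.5))
    frame = geometry.curvature_grid_frame(surf, grid=(5, 5))
    assert list(frame.columns) == ["u", "v", "k"]
    assert np.allclose(frame["k"], 1.0, rtol=1e-8)
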