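"""Regular parametric surfaces and their differential geometry.

A skin patch is modelled as a regular surface: a smooth map
``X(u, v) -> R^3`` on a closed rectangle whose differential is injective
everywhere, i.e. ``E*G - F^2 > 0`` for the first-fundamental-form
coefficients ``E = X_u . X_u``, ``F = X_u . X_v``, ``G = X_v . X_v``.
The module computes first and second fundamental forms, Gaussian
curvature ``k = (e*g - f^2)/(E*G - F^2)``, areas ``A = integral of
sqrt(E*G - F^2) du dv``, geodesic-triangle angle excess via the local
Gauss-Bonnet theorem, curvature suprema, and bed-plane contact regions.

All derivative access is vectorized: derivative callables accept numpy
arrays of parameter values and return arrays whose last axis holds the
three spatial components.  Presets carry closed-form partials; black-box
maps fall back to central finite differences and are flagged as such,
because curvature is second order in the derivatives and difference
noise would otherwise pollute suprema.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Optional

import numpy as np

from .errors import InvalidSpecError, QuadratureError, RegularityError

__all__ = [
    "PatchSpec",
    "ParametricSurface",
    "FundamentalForms",
    "SubDomain",
    "CurvatureSupremum",
    "ContactRegion",
    "make_elliptic_catenoid",
    "make_plane",
    "make_sphere",
    "surface_from_map",
    "fundamental_forms",
    "gaussian_curvature",
    "metric_density",
    "surface_area",
    "angle_excess",
    "curvature_supremum",
    "plane_contact_region",
    "patch_spec_to_text",
    "patch_spec_from_text",
    "curvature_grid_frame",
]

VecField = Callable[[np.ndarray, np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchSpec:
    """Parameters of an elliptic-catenoid skin patch.

    The surface is ``X(u, v) = (a cosh(v/c) cos u, b cosh(v/c) sin u,
    v - d)`` with ``u`` the angular parameter and ``v`` the axial depth.
    ``a`` and ``b`` are the ellipse semi-axes at the waist (m), ``c`` the
    catenoid scale (m) controlling how quickly the cross-section flares,
    and ``d`` a pure z-offset (m).
    """

    a: float
    b: float
    c: float
    d: float = 0.0
    u_range: tuple[float, float] = (0.0, math.pi)
    v_range: tuple[float, float] = (0.0, 0.34)

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InvalidSpecError(
                f"semi-axes and catenoid scale must be positive, got "
                f"a={self.a}, b={self.b}, c={self.c}"
            )
        if not self.depth > 0:
            raise InvalidSpecError(f"patch depth must be positive, got v_range={self.v_range}")
        if not self.u_range[1] > self.u_range[0]:
            raise InvalidSpecError(f"empty angular range {self.u_range}")
        for val in (self.a, self.b, self.c, self.d):
            if not math.isfinite(val):
                raise InvalidSpecError("non-finite patch parameter")

    @property
    def depth(self) -> float:
        return self.v_range[1] - self.v_range[0]

    def with_params(self, **kwargs) -> "PatchSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FundamentalForms:
    """First (E, F, G) and second (e, f, g) fundamental-form coefficients.

    Scalar for point queries, arrays for vectorized queries.
    """

    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    e: np.ndarray
    f: np.ndarray
    g: np.ndarray

    @property
    def metric_determinant(self) -> np.ndarray:
        """``E*G - F^2``; positive wherever the surface is regular."""
        return self.E * self.G - self.F**2


@dataclass(frozen=True)
class SubDomain:
    """A rectangle or triangle in (u, v) parameter space."""

    kind: str  # "rect" | "triangle"
    bounds: tuple[float, float, float, float] | None = None  # u0, u1, v0, v1
    vertices: np.ndarray | None = None  # (3, 2) for triangles

    @staticmethod
    def rect(u0: float, u1: float, v0: float, v1: float) -> "SubDomain":
        if not (u1 > u0 and v1 > v0):
            raise InvalidSpecError(f"degenerate rectangle ({u0}, {u1}) x ({v0}, {v1})")
        return SubDomain(kind="rect", bounds=(u0, u1, v0, v1))

    @staticmethod
    def triangle(p0, p1, p2) -> "SubDomain":
        verts = np.asarray([p0, p1, p2], dtype=float)
        e1, e2 = verts[1] - verts[0], verts[2] - verts[0]
        area2 = abs(e1[0] * e2[1] - e1[1] * e2[0])
        if area2 == 0.0:
            raise InvalidSpecError("degenerate (collinear) triangle")
        return SubDomain(kind="triangle", vertices=verts)

    def bounding_box(self) -> tuple[float, float, float, float]:
        if self.kind == "rect":
            return self.bounds
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return (lo[0], hi[0], lo[1], hi[1])

    def within(self, domain: tuple[tuple[float, float], tuple[float, float]], tol: float = 1e-12) -> bool:
        u0, u1, v0, v1 = self.bounding_box()
        (du0, du1), (dv0, dv1) = domain
        return u0 >= du0 - tol and u1 <= du1 + tol and v0 >= dv0 - tol and v1 <= dv1 + tol


@dataclass
class ParametricSurface:
    """A map (u, v) -> R^3 with derivative access.

    ``d1`` returns the stacked first partials (X_u, X_v); ``d2`` the
    stacked second partials (X_uu, X_uv, X_vv).  ``mixed_partial(m, n)``
    (optional, closed-form presets only) returns the callable for the
    arbitrary-order partial needed by energy and biharmonic diagnostics.
    ``derivative_mode`` records whether derivatives are closed form or
    finite differences.
    """

    map: VecField
    domain: tuple[tuple[float, float], tuple[float, float]]
    d1: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    d2: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]
    derivative_mode: str = "closed-form"
    name: str = "surface"
    spec: Optional[PatchSpec] = None
    mixed_partial: Optional[Callable[[int, int], VecField]] = None

    def contains(self, u, v, tol: float = 1e-9) -> bool:
        (u0, u1), (v0, v1) = self.domain
        return bool(
            np.all(u >= u0 - tol) and np.all(u <= u1 + tol)
            and np.all(v >= v0 - tol) and np.all(v <= v1 + tol)
        )

    def full_region(self) -> SubDomain:
        (u0, u1), (v0, v1) = self.domain
        return SubDomain.rect(u0, u1, v0, v1)


@dataclass(frozen=True)
class CurvatureSupremum:
    """Supremum of |k| over a region, with its arg-max location."""

    value: float
    u: float
    v: float


@dataclass(frozen=True)
class ContactRegion:
    """Grid cells whose image lies within tol of the bed plane, plus area."""

    mask: np.ndarray  # (nu, nv) boolean, cell centers
    u_centers: np.ndarray
    v_centers: np.ndarray
    area: float


# ---------------------------------------------------------------------------
# Surface factories
# ---------------------------------------------------------------------------


def make_elliptic_catenoid(spec: PatchSpec) -> ParametricSurface:
    """Elliptic catenoid ``(a cosh(v/c) cos u, b cosh(v/c) sin u, v - d)``
    with closed-form partials of every order."""

    a, b, c, d = spec.a, spec.b, spec.c, spec.d

    def partial(m: int, n: int) -> VecField:
        # d^m/du^m cos u = cos(u + m pi/2); d^n/dv^n cosh(v/c) alternates
        # cosh/sinh with a 1/c^n factor.  The z component v - d survives
        # only at orders (0,0) and (0,1).
        def fn(u, v):
            u = np.asarray(u, dtype=float)
            v = np.asarray(v, dtype=float)
            u, v = np.broadcast_arrays(u, v)
            ch = np.cosh(v / c) if n % 2 == 0 else np.sinh(v / c)
            ch = ch / c**n
            x = a * ch * np.cos(u + m * math.pi / 2)
            y = b * ch * np.sin(u + m * math.pi / 2)
            if m == 0 and n == 0:
                z = v - d
            elif m == 0 and n == 1:
                z = np.ones_like(v)
            else:
                z = np.zeros_like(v)
            return np.stack([x, y, z], axis=-1)

        return fn

    x00 = partial(0, 0)
    x10, x01 = partial(1, 0), partial(0, 1)
    x20, x11, x02 = partial(2, 0), partial(1, 1), partial(0, 2)

    return ParametricSurface(
        map=x00,
        domain=(tuple(spec.u_range), tuple(spec.v_range)),
        d1=lambda u, v: (x10(u, v), x01(u, v)),
        d2=lambda u, v: (x20(u, v), x11(u, v), x02(u, v)),
        derivative_mode="closed-form",
        name="elliptic-catenoid",
        spec=spec,
        mixed_partial=partial,
    )


def make_plane(
    u_range: tuple[float, float] = (0.0, 1.0),
    v_range: tuple[float, float] = (0.0, 1.0),
    z0: float = 0.0,
) -> ParametricSurface:
    """The flat chart ``(u, v, z0)``."""

    def x00(u, v):
        u, v = np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
        return np.stack([u, v, np.full_like(u, z0)], axis=-1)

    def partial(m, n):
        def fn(u, v):
            u, v = np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
            out = np.zeros(u.shape + (3,))
            if (m, n) == (0, 0):
                return x00(u, v)
            if (m, n) == (1, 0):
                out[..., 0] = 1.0
            elif (m, n) == (0, 1):
                out[..., 1] = 1.0
            return out

        return fn

    return ParametricSurface(
        map=x00,
        domain=(tuple(u_range), tuple(v_range)),
        d1=lambda u, v: (partial(1, 0)(u, v), partial(0, 1)(u, v)),
        d2=lambda u, v: (partial(2, 0)(u, v), partial(1, 1)(u, v), partial(0, 2)(u, v)),
        derivative_mode="closed-form",
        name="plane",
        mixed_partial=partial,
    )


def make_sphere(
    radius: float,
    u_range: tuple[float, float] = (0.0, 2.0 * math.pi),
    v_range: tuple[float, float] = (0.0, math.pi),
) -> ParametricSurface:
    """Sphere of radius R in the polar chart
    ``(R sin v cos u, R sin v sin u, R cos v)``.

    The chart degenerates at the poles v = 0, pi; quadrature nodes are
    interior so integrals over regions touching a pole remain finite.
    """

    if radius <= 0:
        raise InvalidSpecError(f"radius must be positive, got {radius}")
    R = radius

    def trig(u, v):
        u, v = np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
        return u, v

    def x00(u, v):
        u, v = trig(u, v)
        return np.stack([R * np.sin(v) * np.cos(u), R * np.sin(v) * np.sin(u), R * np.cos(v)], axis=-1)

    def partial(m, n):
        # d^m/du^m cos u = cos(u + m pi/2); d^n/dv^n sin v = sin(v + n pi/2)
        def fn(u, v):
            u, v = trig(u, v)
            cu = np.cos(u + m * math.pi / 2)
            su = np.sin(u + m * math.pi / 2)
            sv = np.sin(v + n * math.pi / 2)
            x = R * sv * cu
            y = R * sv * su
            z = R * np.cos(v + n * math.pi / 2) if m == 0 else np.zeros_like(v)
            return np.stack([x, y, z], axis=-1)

        return fn

    return ParametricSurface(
        map=x00,
        domain=(tuple(u_range), tuple(v_range)),
        d1=lambda u, v: (partial(1, 0)(u, v), partial(0, 1)(u, v)),
        d2=lambda u, v: (partial(2, 0)(u, v), partial(1, 1)(u, v), partial(0, 2)(u, v)),
        derivative_mode="closed-form",
        name="sphere",
        mixed_partial=partial,
    )


def surface_from_map(
    map_fn: VecField,
    domain: tuple[tuple[float, float], tuple[float, float]],
    step_rel: float = 1e-5,
    name: str = "black-box",
) -> ParametricSurface:
    """Wrap a black-box map with central-finite-difference derivatives.

    The step is ``step_rel`` times the domain span per axis.  Results
    computed through this path carry ``derivative_mode ==
    "finite-difference"`` so downstream reports can flag them.
    """

    (u0, u1), (v0, v1) = domain
    hu = step_rel * (u1 - u0)
    hv = step_rel * (v1 - v0)

    def f(u, v):
        u, v = np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
        return np.asarray(map_fn(u, v), dtype=float)

    def d1(u, v):
        xu = (f(u + hu, v) - f(u - hu, v)) / (2 * hu)
        xv = (f(u, v + hv) - f(u, v - hv)) / (2 * hv)
        return xu, xv

    def d2(u, v):
        x0 = f(u, v)
        xuu = (f(u + hu, v) - 2 * x0 + f(u - hu, v)) / hu**2
        xvv = (f(u, v + hv) - 2 * x0 + f(u, v - hv)) / hv**2
        xuv = (
            f(u + hu, v + hv) - f(u + hu, v - hv) - f(u - hu, v + hv) + f(u - hu, v - hv)
        ) / (4 * hu * hv)
        return xuu, xuv, xvv

    return ParametricSurface(
        map=f, domain=domain, d1=d1, d2=d2, derivative_mode="finite-difference", name=name
    )


# ---------------------------------------------------------------------------
# Fundamental forms and curvature
# ---------------------------------------------------------------------------


def fundamental_forms(S: ParametricSurface, u, v) -> FundamentalForms:
    """First and second fundamental forms at (u, v) (scalars or arrays).

    ``e, f, g`` are the second partials projected on the unit normal
    ``n = X_u x X_v / |X_u x X_v|``; a vanishing normal raises
    :class:`RegularityError`.
    """

    xu, xv = S.d1(u, v)
    xuu, xuv, xvv = S.d2(u, v)
    E = np.sum(xu * xu, axis=-1)
    F = np.sum(xu * xv, axis=-1)
    G = np.sum(xv * xv, axis=-1)
    normal = np.cross(xu, xv)
    norm = np.linalg.norm(normal, axis=-1)
    if np.any(norm == 0.0):
        raise RegularityError("degenerate normal |X_u x X_v| = 0: surface not regular here")
    nhat = normal / norm[..., None]
    e = np.sum(xuu * nhat, axis=-1)
    f = np.sum(xuv * nhat, axis=-1)
    g = np.sum(xvv * nhat, axis=-1)
    if np.ndim(E) == 0:
        E, F, G, e, f, g = (float(x) for x in (E, F, G, e, f, g))
    return FundamentalForms(E=E, F=F, G=G, e=e, f=f, g=g)


def gaussian_curvature(S: ParametricSurface, u, v):
    """Gaussian curvature ``k = (e g - f^2)/(E G - F^2)`` (1/m^2)."""

    ff = fundamental_forms(S, u, v)
    det = ff.metric_determinant
    if np.any(np.asarray(det) <= 0.0):
        raise RegularityError("E G - F^2 <= 0: injective-differential condition violated")
    return (ff.e * ff.g - ff.f**2) / det


def metric_density(S: ParametricSurface, u, v):
    """Area element density ``sqrt(E G - F^2)``; needs first partials only."""

    xu, xv = S.d1(u, v)
    E = np.sum(xu * xu, axis=-1)
    F = np.sum(xu * xv, axis=-1)
    G = np.sum(xv * xv, axis=-1)
    det = E * G - F**2
    return np.sqrt(np.maximum(det, 0.0))


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _gl(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(order)
    return x, w


def _panel_nodes(lo: float, hi: float, panels: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on `panels` equal sub-intervals."""
    x, w = _gl(order)
    edges = np.linspace(lo, hi, panels + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * (edges[1] - edges[0])
    nodes = (mids[:, None] + half * x[None, :]).ravel()
    weights = np.tile(half * w, panels)
    return nodes, weights


def _integrate_rect(f, bounds, tol, order=8, max_panels=4096, stats=None):
    u0, u1, v0, v1 = bounds
    prev = None
    panels = 1
    while panels <= max_panels:
        un, uw = _panel_nodes(u0, u1, panels, order)
        vn, vw = _panel_nodes(v0, v1, panels, order)
        U, V = np.meshgrid(un, vn, indexing="ij")
        vals = f(U, V)
        total = float(uw @ vals @ vw)
        if stats is not None:
            stats["nodes_per_axis"] = panels * order
        if prev is not None:
            scale = max(abs(total), abs(prev), 1e-300)
            if abs(total - prev) <= tol * scale:
                return total
        prev = total
        panels *= 2
    raise QuadratureError(
        f"quadrature did not converge to rel tol {tol} within {max_panels} panels per axis"
    )


def _integrate_triangle(f, vertices, tol, order=8, max_panels=4096):
    # Duffy transform: (s, t) in [0,1]^2 -> reference triangle, Jacobian s,
    # then affine to the actual triangle.
    p0, p1, p2 = vertices
    J = np.array([p1 - p0, p2 - p0]).T  # 2x2
    detJ = abs(np.linalg.det(J))

    def g(S, T):
        x = S * (1.0 - T)
        y = S * T
        u = p0[0] + J[0, 0] * x + J[0, 1] * y
        v = p0[1] + J[1, 0] * x + J[1, 1] * y
        return f(u, v) * S * detJ

    return _integrate_rect(g, (0.0, 1.0, 0.0, 1.0), tol, order=order, max_panels=max_panels)


def integrate_scalar(f, region: SubDomain, tol: float = 1e-10) -> float:
    """Adaptive tensor-product Gauss-Legendre integral of f over a region.

    Panels per axis double until successive refinements agree within the
    relative tolerance; non-convergence raises :class:`QuadratureError`.
    """

    if region.kind == "rect":
        return _integrate_rect(f, region.bounds, tol)
    return _integrate_triangle(f, region.vertices, tol)


def surface_area(S: ParametricSurface, region: SubDomain | None = None, tol: float = 1e-10) -> float:
    """Area ``integral sqrt(E G - F^2) du dv`` over the region (m^2)."""

    if region is None:
        region = S.full_region()
    if not region.within(S.domain):
        raise InvalidSpecError("integration region extends outside the surface domain")
    return integrate_scalar(lambda u, v: metric_density(S, u, v), region, tol=tol)


def angle_excess(S: ParametricSurface, triangle: SubDomain, tol: float = 1e-9) -> float:
    """Angle excess ``a1 + a2 + a3 - pi`` of a geodesic triangle, computed
    as the Gauss-Bonnet curvature integral ``integral of k dA`` (radians).

    A rectangular SubDomain is accepted for parameter regions (such as a
    sphere octant in the polar chart) whose image is a geodesic triangle.
    """

    if not triangle.within(S.domain):
        raise InvalidSpecError("triangle extends outside the surface domain")

    def integrand(u, v):
        return gaussian_curvature(S, u, v) * metric_density(S, u, v)

    return integrate_scalar(integrand, triangle, tol=tol)


# ---------------------------------------------------------------------------
# Curvature supremum and contact region
# ---------------------------------------------------------------------------


def curvature_supremum(
    field,
    region: SubDomain | None = None,
    grid: tuple[int, int] = (200, 200),
    refine_iters: int = 5,
    refine_grid: int = 21,
) -> CurvatureSupremum:
    """Supremum of |k| over a rectangular region.

    ``field`` is either a :class:`ParametricSurface` (its Gaussian
    curvature is used) or a closed-form callable ``k(u, v)``.  A dense
    grid scan is followed by local grid refinement around the best cell;
    grid ties break toward the lexicographically smallest (u, v).
    """

    if isinstance(field, ParametricSurface):
        if region is None:
            region = field.full_region()
        k = lambda u, v: gaussian_curvature(field, u, v)
    else:
        if region is None:
            raise InvalidSpecError("a closed-form field needs an explicit region")
        k = field
    if region.kind != "rect":
        raise InvalidSpecError("curvature supremum supports rectangular regions only")

    u0, u1, v0, v1 = region.bounds
    nu, nv = grid
    uu = np.linspace(u0, u1, nu)
    vv = np.linspace(v0, v1, nv)
    U, V = np.meshgrid(uu, vv, indexing="ij")
    vals = np.abs(np.asarray(k(U, V)))
    iu, iv = np.unravel_index(int(np.argmax(vals)), vals.shape)  # first (lexicographic) max
    best_u, best_v, best = uu[iu], vv[iv], float(vals[iu, iv])

    wu = (u1 - u0) / (nu - 1)
    wv = (v1 - v0) / (nv - 1)
    for _ in range(refine_iters):
        lu = np.clip([best_u - wu, best_u + wu], u0, u1)
        lv = np.clip([best_v - wv, best_v + wv], v0, v1)
        uu = np.linspace(lu[0], lu[1], refine_grid)
        vv = np.linspace(lv[0], lv[1], refine_grid)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        vals = np.abs(np.asarray(k(U, V)))
        iu, iv = np.unravel_index(int(np.argmax(vals)), vals.shape)
        if float(vals[iu, iv]) >= best:
            best, best_u, best_v = float(vals[iu, iv]), uu[iu], vv[iv]
        wu /= refine_grid - 1
        wv /= refine_grid - 1
    return CurvatureSupremum(value=best, u=float(best_u), v=float(best_v))


def plane_contact_region(
    S: ParametricSurface,
    z0: float,
    tol_z: float,
    grid: tuple[int, int] = (400, 400),
) -> ContactRegion:
    """Cells whose image lies within ``tol_z`` of the bed plane z = z0.

    The area is the midpoint-rule sum of the metric density over the
    selected cells; an empty contact set gives area 0 (not an error).
    """

    (u0, u1), (v0, v1) = S.domain
    nu, nv = grid
    du = (u1 - u0) / nu
    dv = (v1 - v0) / nv
    uc = u0 + du * (np.arange(nu) + 0.5)
    vc = v0 + dv * (np.arange(nv) + 0.5)
    U, V = np.meshgrid(uc, vc, indexing="ij")
    z = S.map(U, V)[..., 2]
    mask = np.abs(z - z0) <= tol_z
    if mask.any():
        dens = metric_density(S, U, V)
        area = float(np.sum(dens[mask]) * du * dv)
    else:
        area = 0.0
    return ContactRegion(mask=mask, u_centers=uc, v_centers=vc, area=area)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def patch_spec_to_text(spec: PatchSpec) -> str:
    """Plain structured-text form of an elliptic-catenoid spec."""

    return (
        "kind: elliptic-catenoid\n"
        f"a: {spec.a!r}\n"
        f"b: {spec.b!r}\n"
        f"c: {spec.c!r}\n"
        f"d: {spec.d!r}\n"
        f"u_range: {spec.u_range[0]!r} {spec.u_range[1]!r}\n"
        f"v_range: {spec.v_range[0]!r} {spec.v_range[1]!r}\n"
    )


def patch_spec_from_text(text: str) -> PatchSpec:
    fields: dict[str, str] = {}
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    if fields.get("kind") != "elliptic-catenoid":
        raise InvalidSpecError(f"unsupported surface kind {fields.get('kind')!r}")
    try:
        ur = tuple(float(x) for x in fields["u_range"].split())
        vr = tuple(float(x) for x in fields["v_range"].split())
        return PatchSpec(
            a=float(fields["a"]), b=float(fields["b"]), c=float(fields["c"]),
            d=float(fields["d"]), u_range=ur, v_range=vr,
        )
    except KeyError as exc:
        raise InvalidSpecError(f"missing surface field {exc}") from exc


def curvature_grid_frame(S: ParametricSurface, grid: tuple[int, int] = (100, 100)):
    """Gaussian curvature sampled on a grid, as a (u, v, k) DataFrame."""

    import pandas as pd

    (u0, u1), (v0, v1) = S.domain
    uu = np.linspace(u0, u1, grid[0])
    vv = np.linspace(v0, v1, grid[1])
    U, V = np.meshgrid(uu, vv, indexing="ij")
    K = gaussian_curvature(S, U, V)
    return pd.DataFrame({"u": U.ravel(), "v": V.ravel(), "k": np.asarray(K).ravel()})
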