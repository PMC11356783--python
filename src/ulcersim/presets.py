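"""Built-in surfaces, parameter sets and reference curvature fields.

Everything a simulation or test needs is generated here
programmatically: the sacral/upper-back patch used by the worked
scenario, generic test surfaces (plane, sphere, circular catenoid, a
torso-scale catenoid), the calibrated damage-model parameter set, and
the closed-form reference curvature fields published for the back patch
before and after loading.

The back patch: the deformed semi-axes are A = 0.0572 m, B = 0.02744 m
with depth D = 0.092 m and z-offset d = 0.00048 m; the undeformed patch
is recovered by inverting the standard-load strains (a = A/(1+eps_uu),
b = B/(1-eps_vv), D' = D/(1+eps_zz)) and its resting contact area is
0.0121318 m^2 — one sixteenth of an average adult male back.  The
catenoid scale c is calibrated against that resting area (see
:mod:`ulcersim.elasticity`).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import damage, elasticity, geometry
from .errors import InvalidSpecError

__all__ = [
    "RESTING_AREA",
    "DEFORMED_SEMI_AXIS_A",
    "DEFORMED_SEMI_AXIS_B",
    "DEFORMED_DEPTH",
    "DEFORMED_OFFSET",
    "C_BOUNDS",
    "standard_material",
    "standard_load",
    "standard_strain",
    "back_initial",
    "back_deformed",
    "damage_params",
    "k1_reference",
    "k2_reference",
    "preset",
    "available_presets",
    "random_test_surface",
]

# Worked-scenario constants (adult male, 1/16 of the back, pelvic load)
RESTING_AREA = 0.0121318  # m^2, undeformed contact patch
DEFORMED_SEMI_AXIS_A = 0.0572  # m
DEFORMED_SEMI_AXIS_B = 0.02744  # m
DEFORMED_DEPTH = 0.092  # m
DEFORMED_OFFSET = 0.00048  # m, published z-offset of the deformed patch
BODY_MASS = 75.0  # kg
PELVIS_FRACTION = 0.14  # fraction of body weight on the patch
C_BOUNDS = (0.05, 10.0)  # m, search range for the catenoid scale


def standard_material() -> elasticity.MaterialProperties:
    return elasticity.MaterialProperties()


def standard_load() -> elasticity.LoadSpec:
    return elasticity.LoadSpec.body_segment(
        body_mass=BODY_MASS, segment_fraction=PELVIS_FRACTION, contact_area=RESTING_AREA
    )


def standard_strain() -> elasticity.StrainState:
    """Strain state of the back patch under the standard pelvic load."""
    sigma = elasticity.contact_stress(standard_load())
    return elasticity.hooke_strain(standard_material(), sigma)


@lru_cache(maxsize=None)
def _calibration() -> elasticity.CalibrationResult:
    eps = standard_strain()
    a = DEFORMED_SEMI_AXIS_A / (1.0 + eps.eps_uu)
    b = DEFORMED_SEMI_AXIS_B / (1.0 - eps.eps_vv)
    depth = DEFORMED_DEPTH / (1.0 + eps.eps_zz)
    return elasticity.calibrate_c(a, b, depth, RESTING_AREA, bounds=C_BOUNDS)


@lru_cache(maxsize=None)
def back_initial() -> geometry.PatchSpec:
    """Undeformed back patch: semi-axes inverted from the deformed ones
    under the standard strain, c calibrated to the resting area."""
    eps = standard_strain()
    cal = _calibration()
    return geometry.PatchSpec(
        a=DEFORMED_SEMI_AXIS_A / (1.0 + eps.eps_uu),
        b=DEFORMED_SEMI_AXIS_B / (1.0 - eps.eps_vv),
        c=cal.c,
        d=0.0,
        u_range=(0.0, np.pi),
        v_range=(0.0, DEFORMED_DEPTH / (1.0 + eps.eps_zz)),
    )


@lru_cache(maxsize=None)
def back_deformed() -> geometry.PatchSpec:
    """Deformed back patch with the published semi-axes, depth and
    offset, sharing the calibrated c of the initial shape."""
    cal = _calibration()
    return geometry.PatchSpec(
        a=DEFORMED_SEMI_AXIS_A,
        b=DEFORMED_SEMI_AXIS_B,
        c=cal.c,
        d=DEFORMED_OFFSET,
        u_range=(0.0, np.pi),
        v_range=(0.0, DEFORMED_DEPTH),
    )


def calibration_info() -> elasticity.CalibrationResult:
    """Details of the c calibration (value, residual, bound status)."""
    return _calibration()


# ---------------------------------------------------------------------------
# Damage-model parameter sets
# ---------------------------------------------------------------------------


def damage_params(name: str = "baseline-adult") -> damage.DamageParams:
    """Named damage-model parameter sets (rates per day).

    ``"baseline-adult"`` is the calibrated cascade: cell regeneration
    r0 = 0.5/d (about a two-day epidermal turnover), neutrophil kill
    coefficient kN1 = 1.68/d per unit density (critical density
    I* = r0/kN1 ~ 0.3 of capacity), neutrophil growth kN2 = 0.36/d,
    DAMP-driven recruitment kD0 = 0.025/d, DAMP production kD1 = 1/d
    and clearance kD2 = 2/d (half-life ~8 h), normalized capacities
    K0 = K1 = 1 (K1 is indicative only), and a Hill oxygen coupling
    with midpoint 25 mmHg, exponent 4 and reference 40 mmHg.

    ``"no-immune"`` switches the neutrophil coupling off (kN1 = kD0 =
    0) for tests of the pure logistic limit.
    """

    if name == "baseline-adult":
        return damage.DamageParams(
            r0=0.5, k_n1=1.68, k_n2=0.36, k_d0=0.025, k_d1=1.0, k_d2=2.0,
            K0=1.0, K1=1.0, hill_p50=25.0, hill_exp=4.0, p_ref=40.0,
            time_unit="days",
        )
    if name == "no-immune":
        return damage.DamageParams(
            r0=0.5, k_n1=0.0, k_n2=0.36, k_d0=0.0, k_d1=1.0, k_d2=2.0,
            K0=1.0, K1=1.0, hill_p50=25.0, hill_exp=4.0, p_ref=40.0,
            time_unit="days",
        )
    raise InvalidSpecError(
        f"unknown damage parameter set {name!r}; available: baseline-adult, no-immune"
    )


# ---------------------------------------------------------------------------
# Reference curvature fields (closed forms published for the back patch)
# ---------------------------------------------------------------------------


def k1_reference(u, v, grouping: str = "sum"):
    """Published closed-form Gaussian curvature of the unloaded back.

    The printed denominator is typographically ambiguous; both candidate
    groupings are retained.  ``"sum"``:
    ``(0.464 cos 2u - 0.961) cosh(0.533 v) + 0.535 cos 2u - 1767.57``;
    ``"product"`` multiplies the leading factor through the whole tail.
    Neither grouping reproduces the published supremum 1.1e-3 (direct
    evaluation gives ~1e-4), so this field is a diagnostic only.
    """

    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    num = np.cosh(0.267 * v) ** 2 * (
        0.00008 * np.sin(2 * u) ** 2 * np.sinh(0.267 * v) ** 2
        + 0.071 * np.cos(2 * u)
        + 0.128
    )
    if grouping == "sum":
        den = (0.464 * np.cos(2 * u) - 0.961) * np.cosh(0.533 * v) + 0.535 * np.cos(2 * u) - 1767.57
    elif grouping == "product":
        den = (0.464 * np.cos(2 * u) - 0.961) * (
            np.cosh(0.533 * v) + 0.535 * np.cos(2 * u) - 1767.57
        )
    else:
        raise InvalidSpecError(f"unknown grouping {grouping!r}; use 'sum' or 'product'")
    return num / den


def k2_reference(u, v):
    """Published closed-form Gaussian curvature of the loaded back:
    numerator ``cosh^2(0.267 v) (-5.6e-5 sin^2(0.533 u) sinh^2(0.267 v)
    - 0.0445 cos(0.533 u) - 0.071)`` over ``-0.6258 cos(0.533 u) +
    cosh(0.533 v) + 13975.9``."""

    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    num = np.cosh(0.267 * v) ** 2 * (
        -0.000056 * np.sin(0.533 * u) ** 2 * np.sinh(0.267 * v) ** 2
        - 0.0445 * np.cos(0.533 * u)
        - 0.071
    )
    den = -0.6258 * np.cos(0.533 * u) + np.cosh(0.533 * v) + 13975.9
    return num / den


# domain over which the published suprema of the reference fields are taken
REFERENCE_FIELD_REGION = geometry.SubDomain.rect(0.0, 2.0 * np.pi, 0.0, 0.34)


# ---------------------------------------------------------------------------
# Catalog access
# ---------------------------------------------------------------------------


def _torso_catenoid() -> geometry.PatchSpec:
    # shoulders-to-pelvis surface of revolution: semi-axes of a torso
    # cross-section; c matches the 1/0.267 scale of the reference
    # curvature fields
    return geometry.PatchSpec(a=0.2, b=0.15, c=3.75, d=0.0, u_range=(0.0, np.pi), v_range=(0.0, 0.34))


_PATCH_PRESETS = {
    "back-initial": back_initial,
    "back-deformed": back_deformed,
    "torso-catenoid": _torso_catenoid,
    "circular-catenoid": lambda: geometry.PatchSpec(
        a=1.0, b=1.0, c=1.0, d=0.0, u_range=(0.0, 2.0 * np.pi), v_range=(0.0, 1.0)
    ),
}

_SURFACE_PRESETS = {
    "unit-sphere": lambda: geometry.make_sphere(1.0),
    "test-plane": lambda: geometry.make_plane(),
}

_FIELD_PRESETS = {
    "k1-reference": lambda: k1_reference,
    "k2-reference": lambda: k2_reference,
}

_DAMAGE_PRESETS = ("baseline-adult", "no-immune")


def available_presets() -> list[str]:
    return sorted(
        list(_PATCH_PRESETS) + list(_SURFACE_PRESETS) + list(_FIELD_PRESETS) + list(_DAMAGE_PRESETS)
    )


def preset(name: str):
    """Look up a preset by name: a PatchSpec, a ParametricSurface, a
    DamageParams set, or a reference curvature field callable."""

    if name in _PATCH_PRESETS:
        return _PATCH_PRESETS[name]()
    if name in _SURFACE_PRESETS:
        return _SURFACE_PRESETS[name]()
    if name in _FIELD_PRESETS:
        return _FIELD_PRESETS[name]()
    if name in _DAMAGE_PRESETS:
        return damage_params(name)
    raise InvalidSpecError(
        f"unknown preset {name!r}; available presets: {', '.join(available_presets())}"
    )


def random_test_surface(seed: int) -> geometry.ParametricSurface:
    """Reproducible random elliptic catenoid for property-based tests:
    a, b in [0.02, 0.1] m, c in [0.5, 5] m; same seed, same surface."""

    rng = np.random.default_rng(seed)
    spec = geometry.PatchSpec(
        a=float(rng.uniform(0.02, 0.1)),
        b=float(rng.uniform(0.02, 0.1)),
        c=float(rng.uniform(0.5, 5.0)),
        d=0.0,
        u_range=(0.0, np.pi),
        v_range=(0.0, 0.15),
    )
    surf = geometry.make_elliptic_catenoid(spec)
    surf.name = f"random-catenoid-{seed}"
    return surf
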