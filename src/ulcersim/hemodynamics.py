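"""Microcirculatory consequences of skin deformation.

Two effects translate geometry into an oxygen supply value for the
damage model:

* **Capillary-density dilution** — the same capillaries spread over a
  larger deformed area, so the density (and with it delivery per unit
  area) scales by ``area_initial / area_deformed``.

* **Curved-tube flow correction** — a capillary following a surface of
  Gaussian curvature k bends with tube-radius-to-bend-radius ratio
  ``delta = r sqrt(|k|)``.  Topakoglu's perturbation result for laminar
  flow in a slightly curved pipe gives the flow relative to a straight
  tube as ``Q_c/Q_s = 1 - (delta^2 / 48) * 1.5416 / (7.2 n^2 + 1.1 n -
  1)`` with n the (tiny) capillary Reynolds number; the deformation's
  effect is the ratio of this correction after to before.  For
  physiological curvatures delta is of order 1e-8, so the correction is
  one to within rounding — the density dilution carries the effect.

The delivered oxygen partial pressure is taken proportional to both
ratios: ``pO2 = baseline * density_ratio * flow_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidSpecError, SingularParameterError

__all__ = [
    "CapillaryBed",
    "FlowState",
    "capillary_density_ratio",
    "tube_deflection",
    "topakoglu_ratio",
    "flow_change_ratio",
    "perfusion_oxygen",
]

TOPAKOGLU_COEFF = 1.5416


@dataclass(frozen=True)
class CapillaryBed:
    """Microvascular bed constants: average capillary diameter 19.5 um,
    Reynolds number ~7e-3, resting tissue pO2 40 mmHg."""

    vessel_diameter: float = 19.5e-6  # m
    reynolds_n: float = 7e-3
    baseline_pO2: float = 40.0  # mmHg

    def __post_init__(self) -> None:
        if self.vessel_diameter <= 0 or self.reynolds_n <= 0 or self.baseline_pO2 <= 0:
            raise InvalidSpecError("capillary-bed constants must be positive")

    @property
    def vessel_radius(self) -> float:
        return 0.5 * self.vessel_diameter


@dataclass(frozen=True)
class FlowState:
    """Relative capillary availability, flow change and resulting pO2."""

    density_ratio: float
    flow_ratio: float
    pO2: float  # mmHg

    def __post_init__(self) -> None:
        if self.density_ratio <= 0:
            raise InvalidSpecError(f"density ratio must be positive, got {self.density_ratio}")
        if self.pO2 < 0:
            raise InvalidSpecError(f"pO2 must be non-negative, got {self.pO2}")


def capillary_density_ratio(area_initial: float, area_deformed: float) -> float:
    """Post-deformation capillary density relative to baseline,
    ``area_initial / area_deformed`` (< 1 when the area grows)."""

    if area_initial <= 0 or area_deformed <= 0:
        raise InvalidSpecError(
            f"areas must be positive, got {area_initial} and {area_deformed}"
        )
    return area_initial / area_deformed


def tube_deflection(sup_k: float, vessel_radius: float) -> float:
    """Dimensionless tube bend ``delta = r sqrt(sup |k|)``: vessel radius
    over the surface's tightest radius of curvature."""

    if sup_k < 0:
        raise InvalidSpecError(f"curvature supremum must be non-negative, got {sup_k}")
    if vessel_radius <= 0:
        raise InvalidSpecError(f"vessel radius must be positive, got {vessel_radius}")
    return vessel_radius * sup_k**0.5


def topakoglu_ratio(delta: float, n: float) -> float:
    """Flow in a slightly curved tube relative to a straight one.

    ``1 - (1/48) delta^2 * 1.5416 / (7.2 n^2 + 1.1 n - 1)``; for the
    microvascular n ~ 7e-3 the denominator is negative, so curvature
    nudges the ratio just above one, by an O(delta^2) amount.
    """

    denom = 7.2 * n**2 + 1.1 * n - 1.0
    if abs(denom) < 1e-12:
        raise SingularParameterError(f"Topakoglu denominator vanishes at n={n}")
    return 1.0 - delta**2 / 48.0 * TOPAKOGLU_COEFF / denom


def flow_change_ratio(delta1: float, delta2: float, n: float) -> float:
    """Flow before deformation over flow after: the ratio of the
    Topakoglu corrections at bends delta1 (before) and delta2 (after)."""

    return topakoglu_ratio(delta1, n) / topakoglu_ratio(delta2, n)


def perfusion_oxygen(bed: CapillaryBed, density_ratio: float, flow_ratio: float) -> FlowState:
    """Delivered oxygen pressure under the proportional-delivery
    assumption: ``pO2 = baseline * density_ratio * flow_ratio``."""

    if density_ratio <= 0 or flow_ratio <= 0:
        raise InvalidSpecError("ratios must be positive")
    p = bed.baseline_pO2 * density_ratio * flow_ratio
    return FlowState(density_ratio=density_ratio, flow_ratio=flow_ratio, pO2=p)
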