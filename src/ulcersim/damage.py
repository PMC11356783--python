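"""Cell-death / neutrophil / DAMP dynamics under pressure-induced hypoxia.

State variables: ``N`` the normalized live-cell population of the skin
patch (fraction of carrying capacity K0), ``I`` the neutrophil density,
``D`` the density of damage-associated molecular patterns (DAMPs, the
debris shed by dying cells that recruits immune cells).  Oxygen enters
through a normalized Hill factor ``H(p) = h(p)/h(p_ref)`` with
``h(p) = p^m / (p^m + p50^m)``, equal to one at the reference pressure.

The coupled system (rates in the declared time unit):

* cells:       ``dN/dt = r0 N (1 - N / (K0 H(p))) - kN1 I N``
* neutrophils: ``dI/dt = kN2 I (1 - I / K1) + kD0 D``
* DAMPs:       ``dD/dt = (1 - N / K0) kD1 - kD2 D``

Hypoxia lowers the effective carrying capacity to ``K0 H``; the small
standing gap ``1 - N/K0`` produces DAMPs, DAMPs seed neutrophil growth,
and once ``I`` exceeds the critical density ``I* = r0 / kN1`` the kill
term overwhelms regeneration and the population collapses — the
pressure-ulcer cascade.  Two alternative readings of the cell equation
are retained behind ``mode``: ``"cc-factored"`` multiplies the whole
bracket by the net growth rate (it is unstable whenever N sits above
the hypoxic capacity while I > I*, which pressure-relief schedules make
unavoidable, hence not the default), and ``"rs"`` applies H as a rate
scale (from which damage cannot nucleate at the healthy equilibrium).

Repositioning is a square wave: the patch alternates between the loaded
oxygen pressure and full relief (H restored to 1), loaded phase first,
with the standard-of-care period of 2 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidSpecError

__all__ = [
    "DamageParams",
    "DamageState",
    "PressureSchedule",
    "Trajectory",
    "EventTimes",
    "hill",
    "rhs",
    "simulate",
    "event_times",
    "reference_rk4",
]

MODES = ("cc", "cc-factored", "rs")
_H_FLOOR = 1e-9  # H -> 0 limit handled as a hard capacity collapse


@dataclass(frozen=True)
class DamageParams:
    """Rate constants, capacities and Hill parameters of the cascade.

    ``time_unit`` declares the unit of all rates ("days" or "hours");
    the integrator converts internally to hours.
    """

    r0: float  # cell reproduction rate (1/time)
    k_n1: float  # neutrophil kill coefficient (1/(time * density))
    k_n2: float  # neutrophil growth rate (1/time)
    k_d0: float  # DAMP -> neutrophil recruitment (1/time)
    k_d1: float  # DAMP production rate (density/time)
    k_d2: float  # DAMP clearance rate (1/time)
    K0: float = 1.0  # cell carrying capacity (normalized)
    K1: float = 1.0  # neutrophil capacity
    hill_p50: float = 25.0  # mmHg
    hill_exp: float = 4.0
    p_ref: float = 40.0  # mmHg, pressure at which H = 1
    time_unit: str = "days"

    def __post_init__(self) -> None:
        for name in ("r0", "k_n1", "k_n2", "k_d0", "k_d1", "k_d2"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"rate {name} must be non-negative")
        if self.K0 <= 0 or self.K1 <= 0:
            raise InvalidSpecError("capacities K0, K1 must be positive")
        if self.hill_p50 <= 0 or self.hill_exp <= 0 or self.p_ref <= 0:
            raise InvalidSpecError("Hill parameters must be positive")
        if self.time_unit not in ("days", "hours"):
            raise InvalidSpecError(f"unknown time unit {self.time_unit!r}")

    def per_hour(self) -> "DamageParams":
        """Copy with all rates converted to 1/hour."""
        if self.time_unit == "hours":
            return self
        s = 1.0 / 24.0
        return replace(
            self,
            r0=self.r0 * s, k_n1=self.k_n1 * s, k_n2=self.k_n2 * s,
            k_d0=self.k_d0 * s, k_d1=self.k_d1 * s, k_d2=self.k_d2 * s,
            time_unit="hours",
        )

    @property
    def critical_neutrophil_density(self) -> float:
        """I* = r0 / kN1, above which the kill term beats regeneration."""
        return math.inf if self.k_n1 == 0 else self.r0 / self.k_n1


@dataclass(frozen=True)
class DamageState:
    """Instantaneous state (N, I, D) at time t (hours)."""

    N: float
    I: float
    D: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 0 or self.I < 0 or self.D < 0:
            raise InvalidSpecError("state components must be non-negative")


def default_initial_state(params: DamageParams) -> DamageState:
    """Near-healthy initial conditions: N0 = 0.99 K0 and a small
    neutrophil seed I0 = 1e-3 K1 from which a response can nucleate."""

    return DamageState(N=0.99 * params.K0, I=1e-3 * params.K1, D=0.0)


@dataclass(frozen=True)
class PressureSchedule:
    """Constant load or 2-h repositioning square wave (loaded first).

    During relieved phases the oxygen availability is fully restored:
    H is forced to 1 (equivalently p = p_ref).
    """

    loaded_p: float  # mmHg
    kind: str = "constant"  # "constant" | "periodic"
    period_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.loaded_p < 0:
            raise InvalidSpecError(f"loaded pressure must be non-negative, got {self.loaded_p}")
        if self.kind not in ("constant", "periodic"):
            raise InvalidSpecError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "periodic" and self.period_hours <= 0:
            raise InvalidSpecError(f"period must be positive, got {self.period_hours}")

    def pressure_at(self, t_hours: float, p_ref: float) -> float:
        if self.kind == "constant":
            return self.loaded_p
        phase = int(t_hours // self.period_hours) % 2
        return self.loaded_p if phase == 0 else p_ref

    def segments(self, t_end_hours: float) -> Iterator[tuple[float, float, bool]]:
        """(t0, t1, loaded) pieces covering [0, t_end]; integration is
        restarted exactly at each boundary."""
        if self.kind == "constant":
            yield (0.0, t_end_hours, True)
            return
        t = 0.0
        loaded = True
        while t < t_end_hours:
            t1 = min(t + self.period_hours, t_end_hours)
            yield (t, t1, loaded)
            t, loaded = t1, not loaded


@dataclass
class Trajectory:
    """Dense simulation output with solver metadata.

    ``frame`` columns: t_hours, t_days, N, I, D, p_mmHg, H.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        out = self.frame[["t_days", "N", "I", "D", "p_mmHg", "H"]]
        out.to_csv(path, index=False, float_format="%.10g")

    def final_state(self) -> DamageState:
        row = self.frame.iloc[-1]
        return DamageState(N=row.N, I=row.I, D=row.D, t=row.t_hours)


@dataclass(frozen=True)
class EventTimes:
    """Threshold-crossing times in days; None when never crossed."""

    t_onset_days: Optional[float]
    t_destruction_days: Optional[float]


# ---------------------------------------------------------------------------
# Model right-hand side
# ---------------------------------------------------------------------------


def hill(p: float, params: DamageParams) -> float:
    """Normalized Hill factor ``H(p) = h(p)/h(p_ref)`` in (0, 1] for
    p <= p_ref; H(0) = 0, H(p_ref) = 1, monotone increasing."""

    if p < 0:
        raise InvalidSpecError(f"pressure must be non-negative, got {p}")
    m, p50 = params.hill_exp, params.hill_p50
    h = p**m / (p**m + p50**m) if p > 0 else 0.0
    href = params.p_ref**m / (params.p_ref**m + p50**m)
    return h / href


def _dN(N: float, I: float, H: float, q: DamageParams, mode: str) -> float:
    H = max(H, _H_FLOOR)
    if mode == "cc":
        return q.r0 * N * (1.0 - N / (q.K0 * H)) - q.k_n1 * I * N
    if mode == "cc-factored":
        return (q.r0 - q.k_n1 * I) * (1.0 - N / (q.K0 * H)) * N
    if mode == "rs":
        return (q.r0 - q.k_n1 * I) * (1.0 - N / q.K0) * H * N
    raise InvalidSpecError(f"unknown mode {mode!r}; choose from {MODES}")


def rhs(
    t: float,
    state,
    params: DamageParams,
    schedule: PressureSchedule,
    mode: str = "cc",
) -> tuple[float, float, float]:
    """(dN/dt, dI/dt, dD/dt) at time t (hours) under the schedule."""

    q = params.per_hour()
    N, I, D = (state.N, state.I, state.D) if isinstance(state, DamageState) else state
    p = schedule.pressure_at(t, q.p_ref)
    H = hill(p, q)
    dN = _dN(N, I, H, q, mode)
    dI = q.k_n2 * I * (1.0 - I / q.K1) + q.k_d0 * D
    dD = (1.0 - N / q.K0) * q.k_d1 - q.k_d2 * D
    return (dN, dI, dD)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def simulate(
    params: DamageParams,
    schedule: PressureSchedule,
    t_end_hours: float,
    init: Optional[DamageState] = None,
    rtol: float = 1e-8,
    atol: float = 1e-11,
    mode: str = "cc",
    samples_per_hour: float = 4.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the cascade with a stiff-capable adaptive solver.

    Integration restarts exactly at every schedule discontinuity; the
    trajectory is sampled densely (>= ``samples_per_hour``).  Negative
    undershoots within solver tolerance are clipped to zero and the
    clip count recorded in the metadata.
    """

    if t_end_hours <= 0:
        raise InvalidSpecError(f"t_end must be positive, got {t_end_hours}")
    if mode not in MODES:
        raise InvalidSpecError(f"unknown mode {mode!r}; choose from {MODES}")
    q = params.per_hour()
    if init is None:
        init = default_initial_state(params)

    n_samples = int(math.ceil(t_end_hours * samples_per_hour)) + 1
    t_grid = np.linspace(0.0, t_end_hours, n_samples)
    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    rows_p: list[np.ndarray] = []
    rows_H: list[np.ndarray] = []

    y = np.array([init.N, init.I, init.D], dtype=float)
    for (t0, t1, loaded) in schedule.segments(t_end_hours):
        p = schedule.loaded_p if loaded else q.p_ref
        H = hill(p, q)

        def seg_rhs(t, yy, H=H):
            N, I, D = yy
            return [
                _dN(N, I, H, q, mode),
                q.k_n2 * I * (1.0 - I / q.K1) + q.k_d0 * D,
                (1.0 - N / q.K0) * q.k_d1 - q.k_d2 * D,
            ]

        sol = solve_ivp(
            seg_rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol, dense_output=True
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed in [{t0}, {t1}] h: {sol.message}", last_time=float(sol.t[-1])
            )
        mask = (t_grid >= t0 - 1e-12) & (t_grid < t1) if t1 < t_end_hours else (
            (t_grid >= t0 - 1e-12) & (t_grid <= t1 + 1e-12)
        )
        ts = t_grid[mask]
        ys = sol.sol(ts)
        rows_t.append(ts)
        rows_y.append(ys)
        rows_p.append(np.full_like(ts, p))
        rows_H.append(np.full_like(ts, H))
        y = sol.y[:, -1]

    t_all = np.concatenate(rows_t)
    y_all = np.concatenate(rows_y, axis=1)
    clip_tol = 100.0 * atol
    below = y_all < 0.0
    n_clipped = int(np.count_nonzero(below))
    if np.any(y_all < -clip_tol):
        worst = float(y_all.min())
        raise IntegrationError(
            f"state undershoot {worst} exceeds the clipping tolerance {clip_tol}"
        )
    y_all = np.clip(y_all, 0.0, None)

    frame = pd.DataFrame(
        {
            "t_hours": t_all,
            "t_days": t_all / 24.0,
            "N": y_all[0],
            "I": y_all[1],
            "D": y_all[2],
            "p_mmHg": np.concatenate(rows_p),
            "H": np.concatenate(rows_H),
        }
    )
    meta = {
        "mode": mode,
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "samples_per_hour": samples_per_hour,
        "clipped_samples": n_clipped,
        "schedule_kind": schedule.kind,
        "loaded_p_mmHg": schedule.loaded_p,
        "period_hours": schedule.period_hours if schedule.kind == "periodic" else None,
        "initial_state": {"N": init.N, "I": init.I, "D": init.D},
        "time_unit_declared": params.time_unit,
    }
    return Trajectory(frame=frame, metadata=meta)


def event_times(
    traj: Trajectory,
    onset_fraction: float = 0.9,
    destruction_level: float = 0.05,
) -> EventTimes:
    """First crossing times of the damage thresholds, in days.

    Onset: N first drops below ``onset_fraction`` of its initial value
    ("visible tissue damage").  Destruction: N first drops below
    ``destruction_level`` in absolute terms.  Crossings are located by
    linear interpolation between trajectory samples; absent crossings
    are reported as None.
    """

    if len(traj.frame) == 0:
        raise InvalidSpecError("empty trajectory")
    t = traj.frame["t_days"].to_numpy()
    N = traj.frame["N"].to_numpy()

    def first_crossing(level: float) -> Optional[float]:
        below = N < level
        if not below.any():
            return None
        i = int(np.argmax(below))
        if i == 0:
            return float(t[0])
        # linear interpolation across the bracketing samples
        f = (N[i - 1] - level) / (N[i - 1] - N[i])
        return float(t[i - 1] + f * (t[i] - t[i - 1]))

    return EventTimes(
        t_onset_days=first_crossing(onset_fraction * N[0]),
        t_destruction_days=first_crossing(destruction_level),
    )


def reference_rk4(
    params: DamageParams,
    schedule: PressureSchedule,
    t_end_hours: float,
    init: Optional[DamageState] = None,
    step_hours: float = 0.01,
    mode: str = "cc",
) -> DamageState:
    """Fixed-step classical Runge-Kutta reference integrator.

    Steps are aligned with schedule discontinuities.  Used as an
    independent oracle for the adaptive solver; O(h^4) accurate.
    """

    q = params.per_hour()
    if init is None:
        init = default_initial_state(params)
    y = np.array([init.N, init.I, init.D], dtype=float)

    for (t0, t1, loaded) in schedule.segments(t_end_hours):
        p = schedule.loaded_p if loaded else q.p_ref
        H = hill(p, q)

        def f(yy):
            N, I, D = yy
            return np.array(
                [
                    _dN(N, I, H, q, mode),
                    q.k_n2 * I * (1.0 - I / q.K1) + q.k_d0 * D,
                    (1.0 - N / q.K0) * q.k_d1 - q.k_d2 * D,
                ]
            )

        n_steps = max(1, int(math.ceil((t1 - t0) / step_hours)))
        h = (t1 - t0) / n_steps
        for _ in range(n_steps):
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    return DamageState(N=max(y[0], 0.0), I=max(y[1], 0.0), D=max(y[2], 0.0), t=t_end_hours)
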