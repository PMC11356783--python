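"""Cell-death / neutrophil / DAMP cascade: equilibria, limits, solvers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulcersim import damage, presets
from ulcersim.damage import DamageState, PressureSchedule, Trajectory
from ulcersim.errors import InvalidSpecError

PARAMS = presets.damage_params("baseline-adult")


def test_hill_normalization_and_limits():
    assert damage.hill(PARAMS.p_ref, PARAMS) == pytest.approx(1.0, rel=1e-14)
    assert damage.hill(0.0, PARAMS) == 0.0
    # unnormalized midpoint: with a huge reference pressure H(p50) -> 1/2
    from dataclasses import replace

    wide = replace(PARAMS, p_ref=1e9)
    assert damage.hill(wide.hill_p50, wide) == pytest.approx(0.5, rel=1e-6)


@settings(max_examples=50, deadline=None)
@given(p=st.floats(min_value=0.1, max_value=120.0))
def test_hill_monotone_increasing(p):
    assert damage.hill(p + 0.5, PARAMS) > damage.hill(p, PARAMS)


@pytest.mark.parametrize("mode", damage.MODES)
def test_healthy_equilibrium_is_stationary(mode):
    """(N, I, D) = (K0, 0, 0) is a fixed point at full oxygen in every
    equation mode; in the rate-scaling mode it is a fixed point under
    any pressure (which is why damage cannot nucleate there)."""
    state = DamageState(N=PARAMS.K0, I=0.0, D=0.0)
    for t in (0.0, 1.0, 3.0):
        dN, dI, dD = damage.rhs(t, state, PARAMS, PressureSchedule(loaded_p=PARAMS.p_ref), mode=mode)
        assert (dN, dI, dD) == pytest.approx((0.0, 0.0, 0.0), abs=1e-15)
    if mode == "rs":
        dN, dI, dD = damage.rhs(0.0, state, PARAMS, PressureSchedule(loaded_p=20.0), mode=mode)
        assert (dN, dI, dD) == pytest.approx((0.0, 0.0, 0.0), abs=1e-15)
    else:
        # hypoxia pushes K0 above the effective capacity: the healthy
        # point is no longer stationary -- this is how damage nucleates
        dN, _, _ = damage.rhs(0.0, state, PARAMS, PressureSchedule(loaded_p=20.0), mode=mode)
        assert dN < 0.0


def test_full_population_produces_no_damps():
    state = DamageState(N=PARAMS.K0, I=0.3, D=0.2)
    _, _, dD = damage.rhs(0.0, state, PARAMS, PressureSchedule(loaded_p=30.0))
    q = PARAMS.per_hour()
    assert dD == pytest.approx(-q.k_d2 * 0.2, rel=1e-12)


def test_equilibrium_persists_under_simulation():
    traj = damage.simulate(
        PARAMS, PressureSchedule(loaded_p=PARAMS.p_ref), t_end_hours=48.0,
        init=DamageState(N=PARAMS.K0, I=0.0, D=0.0),
    )
    assert np.allclose(traj.frame["N"], PARAMS.K0, atol=1e-8)
    assert np.allclose(traj.frame["I"], 0.0, atol=1e-10)


def test_no_immune_limit_follows_logistic_closed_form():
    """With the immune couplings off and H = 1 the cell equation is a
    pure logistic with rate r0 and capacity K0."""
    par = presets.damage_params("no-immune")
    N0 = 0.2
    traj = damage.simulate(
        par, PressureSchedule(loaded_p=par.p_ref), t_end_hours=5 * 24.0,
        init=DamageState(N=N0, I=0.0, D=0.0),
    )
    q = par.per_hour()
    t = traj.frame["t_hours"].to_numpy()
    expected = q.K0 / (1.0 + (q.K0 / N0 - 1.0) * np.exp(-q.r0 * t))
    assert np.allclose(traj.frame["N"], expected, rtol=1e-6)


def test_rs_mode_cannot_nucleate_damage_from_near_equilibrium():
    """In the rate-scaling reading, hypoxia only slows the approach to
    K0, so N never falls: the motivation for the capacity reading."""
    traj = damage.simulate(
        PARAMS, PressureSchedule(loaded_p=25.0), t_end_hours=10 * 24.0,
        init=DamageState(N=0.99, I=0.0, D=0.0), mode="rs",
    )
    assert traj.frame["N"].iloc[-1] >= 0.99


def test_trajectory_invariants_hold(healthy_result, impaired_result, healthy_repositioned_result):
    for res in (healthy_result, impaired_result, healthy_repositioned_result):
        frame = res.trajectory.frame
        assert (frame["t_hours"].diff().dropna() > 0).all()
        assert float(frame["N"].min()) >= 0.0
        assert float(frame["N"].max()) <= PARAMS.K0 * (1 + 1e-9)
        assert float(frame["I"].min()) >= 0.0
        assert float(frame["D"].min()) >= 0.0
        # neutrophils stay within capacity plus the DAMP-driven overshoot
        assert float(frame["I"].max()) <= PARAMS.K1 * 1.2


def test_sampling_density_and_schedule_columns():
    sched = PressureSchedule(loaded_p=30.0, kind="periodic", period_hours=2.0)
    traj = damage.simulate(PARAMS, sched, t_end_hours=12.0)
    frame = traj.frame
    assert len(frame) >= 4 * 12
    # loaded-first square wave: p alternates between loaded and reference
    assert frame["p_mmHg"].iloc[0] == 30.0
    at_3h = frame.loc[(frame.t_hours - 3.0).abs().idxmin(), "p_mmHg"]
    assert at_3h == PARAMS.p_ref
    assert set(np.round(frame["p_mmHg"].unique(), 9)) == {30.0, PARAMS.p_ref}


def test_schedule_segments_partition_horizon():
    sched = PressureSchedule(loaded_p=30.0, kind="periodic", period_hours=2.0)
    segs = list(sched.segments(7.0))
    assert segs[0] == (0.0, 2.0, True)
    assert segs[-1] == (6.0, 7.0, False)
    assert [s[2] for s in segs] == [True, False, True, False]
    assert [s[0] for s in segs[1:]] == [s[1] for s in segs[:-1]]


def test_adaptive_solver_agrees_with_rk4_oracle():
    """Five-day healthy run: LSODA vs fixed-step RK4 at h = 0.005 h
    agree to 1e-6 relative in every component."""
    sched = PressureSchedule(loaded_p=39.17)
    traj = damage.simulate(PARAMS, sched, t_end_hours=5 * 24.0, rtol=1e-10, atol=1e-13)
    ref = damage.reference_rk4(PARAMS, sched, t_end_hours=5 * 24.0, step_hours=0.005)
    end = traj.final_state()
    assert end.N == pytest.approx(ref.N, rel=1e-6)
    assert end.I == pytest.approx(ref.I, rel=1e-6)
    assert end.D == pytest.approx(ref.D, rel=1e-6)


def test_event_times_tolerance_robustness():
    """Tightening solver tolerances tenfold moves event times < 1%."""
    sched = PressureSchedule(loaded_p=37.0)
    t1 = damage.event_times(damage.simulate(PARAMS, sched, 30 * 24.0, rtol=1e-7, atol=1e-10))
    t2 = damage.event_times(damage.simulate(PARAMS, sched, 30 * 24.0, rtol=1e-8, atol=1e-11))
    assert t1.t_onset_days == pytest.approx(t2.t_onset_days, rel=1e-2)
    assert t1.t_destruction_days == pytest.approx(t2.t_destruction_days, rel=1e-2)


def test_event_times_flat_trajectory_has_no_events():
    frame = pd.DataFrame(
        {"t_hours": [0.0, 24.0], "t_days": [0.0, 1.0], "N": [1.0, 1.0],
         "I": [0, 0], "D": [0, 0], "p_mmHg": [40, 40], "H": [1, 1]}
    )
    ev = damage.event_times(Trajectory(frame=frame))
    assert ev.t_onset_days is None and ev.t_destruction_days is None


def test_event_times_exponential_closed_form():
    """N(t) = exp(-t/tau): onset at tau ln(1/0.9), destruction at
    tau ln(1/0.05)."""
    tau_days = 4.0
    t = np.linspace(0.0, 30.0, 20001)
    frame = pd.DataFrame(
        {"t_hours": t * 24, "t_days": t, "N": np.exp(-t / tau_days),
         "I": 0.0, "D": 0.0, "p_mmHg": 40.0, "H": 1.0}
    )
    ev = damage.event_times(Trajectory(frame=frame))
    assert ev.t_onset_days == pytest.approx(tau_days * math.log(1 / 0.9), rel=1e-4)
    assert ev.t_destruction_days == pytest.approx(tau_days * math.log(1 / 0.05), rel=1e-4)


def test_invalid_inputs_rejected():
    with pytest.raises(InvalidSpecError):
        damage.simulate(PARAMS, PressureSchedule(loaded_p=40.0), t_end_hours=0.0)
    with pytest.raises(InvalidSpecError):
        PressureSchedule(loaded_p=-1.0)
    with pytest.raises(InvalidSpecError):
        PressureSchedule(loaded_p=40.0, kind="periodic", period_hours=0.0)
    with pytest.raises(InvalidSpecError):
        DamageState(N=-0.1, I=0.0, D=0.0)
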