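"""Simplest Walker (two-link passive-dynamic walker) under body-weight support.

The walker is a point mass ``M`` at the hip on two massless legs of length
``l``; the foot mass is negligible (``m/M -> 0``).  ``theta`` is the stance
leg angle from the vertical, ``phi`` the swing leg angle measured from the
stance leg, so that heel strike occurs on the surface ``phi - 2 theta = 0``.
A torsional hip spring of dimensionless stiffness ``k_f`` drives the swing
leg.  Everything here is integrated in dimensionless units: lengths in
units of ``l``, time in units of ``sqrt(l/g)``.

The walker advances in +x with ``theta`` decreasing from ``+theta0`` at the
start of a step (new stance foot ahead of the hip) through zero to
``theta < 0`` at heel strike; the step length is ``-2 sin(theta^-)``.

The vertical unloading force acts at the hip and modifies the equations of
motion per strategy; the impulsive heel-strike map is applied unchanged for
all strategies (a finite unloading force contributes no impulse during an
instantaneous impact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .config import (
    FailureThresholds,
    Model,
    Strategy,
    SWParams,
    Tolerances,
    UnloadingConfig,
)
from .trace import Event, EventKind, SimulationTrace, Termination

#: state vector layout
SW_STATE_NAMES = ("theta", "phi", "theta_dot", "phi_dot")

#: reference gait: a limit cycle at step length 0.7167 l.  The stance rate
#: sets the gait speed; the push-off magnitude follows analytically from
#: periodicity (p = |theta_dot| tan(theta0)) and k_f is calibrated by
#: bisection so the swing leg strikes exactly at the mirror angle
#: (see calibrate_default_gait); these are the package defaults.
DEFAULT_STEP_LENGTH = 0.7167
DEFAULT_THETA_DOT0 = -0.44
DEFAULT_K_F = 1.0626392482014353


def sw_derivatives(
    s: np.ndarray,
    p: SWParams,
    cfg: UnloadingConfig,
) -> np.ndarray:
    """Time derivative of the SW state ``[theta, phi, theta_dot, phi_dot]``.

    Implements the strategy-modified equations of motion in dimensionless
    time.  At ``u = 0`` all three strategies coincide with the unsupported
    level-ground walker with hip spring.
    """
    theta, phi, theta_dot, phi_dot = s
    u = cfg.u
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    sin_p, cos_p = math.sin(phi), math.cos(phi)

    if cfg.strategy is Strategy.CF:
        theta_dd = (1.0 - u) * sin_t
        phi_dd = (
            theta_dd
            + theta_dot**2 * sin_p
            + u * sin_t * cos_p
            - cos_t * sin_p
            - p.k_f * phi
        )
    elif cfg.strategy is Strategy.CW:
        theta_dd = (1.0 - u) / (1.0 + u) * sin_t
        phi_dd = (
            theta_dd
            + theta_dot**2 * sin_p
            - cos_t * sin_p
            + (2.0 * u) / (1.0 + u) * sin_t * cos_p
            - p.k_f * phi
        )
    else:  # tuned spring; lam = (l/g) * omega^2 is the dimensionless tuning
        if u == 0.0:
            lam = 0.0
        else:
            cfg.require_ts()
            lam = (p.l / p.g) * cfg.omega**2
        theta_dd = (1.0 - u) * sin_t + lam * u * (1.0 - cos_t) * sin_t
        phi_dd = (
            theta_dd
            + theta_dot**2 * sin_p
            - cos_t * sin_p
            - u * (1.0 + lam * (1.0 - cos_t)) * sin_t * cos_p
            - p.k_f * phi
        )
    return np.array([theta_dot, phi_dot, theta_dd, phi_dd])


def sw_heelstrike_map(s_pre: np.ndarray, tol: float = 1e-6, pushoff: float = 0.0) -> np.ndarray:
    """Instantaneous leg-exchange map at heel strike, optionally powered.

    Requires the strike condition ``phi - 2 theta = 0``.  The leg roles
    swap (``theta+ = -theta-``, ``phi+ = -2 theta-``) and the post-impact
    rates follow from angular-momentum conservation about the new contact
    point (for the hip) and about the hip (for the new swing leg) in the
    ``m/M -> 0`` limit:

        theta_dot+ = cos(2 theta) theta_dot-  +  sin(2 theta) * pushoff
        phi_dot+   = (1 - cos(2 theta)) theta_dot+

    ``pushoff`` is an impulsive toe-off of dimensionless magnitude applied
    along the trailing leg the instant before the collision; at
    ``pushoff = 0`` this is the purely inelastic exchange map
    (``theta_dot+ = cos(2 theta) theta_dot-``).  The map is applied
    unchanged under all unloading strategies (a finite unloading force
    contributes no impulse during the instantaneous impact).
    """
    theta, phi, theta_dot, _ = s_pre
    if abs(phi - 2.0 * theta) > tol:
        raise ValueError(
            f"heel-strike map called off the strike surface: phi - 2 theta = {phi - 2 * theta:.3e}"
        )
    c2t = math.cos(2.0 * theta)
    theta_dot_post = c2t * theta_dot + math.sin(2.0 * theta) * pushoff
    return np.array(
        [
            -theta,
            -2.0 * theta,
            theta_dot_post,
            (1.0 - c2t) * theta_dot_post,
        ]
    )


def periodic_pushoff(theta0: float, theta_dot: float) -> float:
    """Toe-off magnitude sustaining a symmetric cycle at strike angle ``theta0``.

    During stance the vault conserves energy, so ``|theta_dot|`` at strike
    equals ``|theta_dot|`` at the start of stance; periodicity of the
    exchange map then requires ``p = |theta_dot| tan(theta0)``.
    """
    return abs(theta_dot) * math.tan(theta0)


def sw_initial_state(
    step_length: float = DEFAULT_STEP_LENGTH,
    theta_dot: float = DEFAULT_THETA_DOT0,
    phi_dot: float | None = None,
) -> np.ndarray:
    """Post-impact double-stance pose for a given initial step length.

    ``theta0 = asin(step_length / 2)`` (step length in units of ``l``),
    ``phi0 = 2 theta0``.  The default swing rate is the post-impact value
    consistent with the exchange map, ``(1 - cos(2 theta0)) theta_dot``.
    """
    if not (0.0 < step_length < 2.0):
        raise ValueError(f"step_length={step_length} outside (0, 2)")
    theta0 = math.asin(step_length / 2.0)
    if phi_dot is None:
        phi_dot = (1.0 - math.cos(2.0 * theta0)) * theta_dot
    return np.array([theta0, 2.0 * theta0, theta_dot, phi_dot])


def swing_foot_height(s: np.ndarray) -> float:
    """Swing-foot clearance in units of ``l``: cos(theta) - cos(phi - theta)."""
    theta, phi = s[0], s[1]
    return math.cos(theta) - math.cos(phi - theta)


@dataclass
class _StepOutcome:
    state: np.ndarray
    t: float
    termination: Termination | None


def simulate_sw(
    params: SWParams,
    cfg: UnloadingConfig,
    init: np.ndarray,
    step_budget: int = 20,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
) -> SimulationTrace:
    """Hybrid stride-by-stride integration of the Simplest Walker.

    Integrates the smooth stance/swing dynamics between heel strikes,
    applies the leg-exchange map at each strike, and terminates on the step
    budget or on a failure predicate (hip collapse, stance reversal,
    non-forward step).
    """
    if step_budget < 1:
        raise ValueError(f"step_budget={step_budget} must be >= 1")
    tolerances = tolerances or Tolerances()
    failure = failure or FailureThresholds()

    state = np.asarray(init, dtype=float)
    if state.shape != (4,) or not np.all(np.isfinite(state)):
        raise ValueError("init must be a finite state [theta, phi, theta_dot, phi_dot]")

    def rhs(t, y):
        return sw_derivatives(y, params, cfg)

    def ev_strike(t, y):
        return y[1] - 2.0 * y[0]

    ev_strike.terminal = True
    ev_strike.direction = 1.0  # genuine strike: phi - 2 theta crosses zero upward

    def ev_reversal(t, y):
        return y[2]

    ev_reversal.terminal = True
    ev_reversal.direction = 1.0  # stance rate rising through zero: vault failed

    def ev_collapse(t, y):
        return math.cos(y[0]) - failure.sw_min_cos_theta

    ev_collapse.terminal = True
    ev_collapse.direction = -1.0

    events = (ev_strike, ev_reversal, ev_collapse)
    # the post-impact state sits exactly on the strike surface (phi = 2 theta),
    # which a root finder would report as an immediate event; integrate a short
    # guard interval without the strike event after each impact
    guard = 1e-4

    t = 0.0
    foot_x = 0.0
    com_x0 = foot_x - math.sin(state[0])

    times = [t]
    states = [state.copy()]
    com_x = [com_x0]
    com_y = [math.cos(state[0])]
    phases = ["stance"]
    ev_log: list[Event] = []
    legs = ("left", "right")
    stance_idx = 0  # initial stance leg: left
    steps = 0
    termination = None

    on_surface = True  # initial pose is the post-impact double stance
    while steps < step_budget:
        if on_surface:
            pre = solve_ivp(
                rhs,
                (t, t + guard),
                state,
                method="RK45",
                rtol=tolerances.rtol,
                atol=tolerances.atol,
                events=events[1:],
            )
            if not pre.success or pre.status == 1:
                termination = (
                    Termination.INTEGRATION_FAILURE
                    if not pre.success
                    else Termination.MOVED_BACKWARD
                    if len(pre.t_events[0])
                    else Termination.FELL
                )
                t, state = pre.t[-1], pre.y[:, -1]
                break
            t, state = pre.t[-1], pre.y[:, -1]
            on_surface = False
        sol = solve_ivp(
            rhs,
            (t, t + failure.max_step_time),
            state,
            method="RK45",
            rtol=tolerances.rtol,
            atol=tolerances.atol,
            max_step=tolerances.max_step,
            events=events,
            dense_output=False,
        )
        if not sol.success:
            termination = Termination.INTEGRATION_FAILURE
            break

        # append the smooth segment (skip duplicate first sample)
        seg_t = sol.t[1:]
        seg_y = sol.y[:, 1:].T
        times.extend(seg_t.tolist())
        states.extend(list(seg_y))
        com_x.extend((foot_x - np.sin(seg_y[:, 0])).tolist())
        com_y.extend(np.cos(seg_y[:, 0]).tolist())
        phases.extend(["stance"] * len(seg_t))

        if sol.status != 1:
            # ran to the horizon without any event: treat as failed integration
            termination = Termination.INTEGRATION_FAILURE
            t = sol.t[-1]
            state = sol.y[:, -1]
            break

        # identify which terminal event fired (the earliest)
        hit = [(te[0], i) for i, te in enumerate(sol.t_events) if len(te)]
        t_ev, which = min(hit)
        y_ev = sol.y_events[which][0]

        if which == 1:
            termination = Termination.MOVED_BACKWARD
            t, state = t_ev, y_ev
            break
        if which == 2:
            termination = Termination.FELL
            t, state = t_ev, y_ev
            break

        # heel-strike surface crossing
        theta_minus = y_ev[0]
        if abs(theta_minus) <= failure.sw_heelstrike_theta_min:
            # spurious double root near theta = 0: resume integration just past it
            t, state = t_ev, y_ev
            on_surface = True  # resuming from the surface needs the guard again
            continue
        if theta_minus > 0.0:
            # swing foot lands behind the hip: no forward progress
            termination = Termination.MOVED_BACKWARD
            t, state = t_ev, y_ev
            break

        # genuine heel strike: advance the stance foot and swap leg roles
        step_len = -2.0 * math.sin(theta_minus)
        foot_x += step_len
        state = sw_heelstrike_map(y_ev, tol=1e-6, pushoff=params.pushoff)
        t = t_ev
        steps += 1
        on_surface = True
        stance_idx = 1 - stance_idx
        ev_log.append(Event(t, EventKind.HEELSTRIKE, legs[stance_idx]))

        # record the post-impact sample at the same time stamp
        times.append(t)
        states.append(state.copy())
        com_x.append(foot_x - math.sin(state[0]))
        com_y.append(math.cos(state[0]))
        phases.append("stance")

    if termination is None:
        termination = Termination.STEP_BUDGET_REACHED

    n = len(times)
    return SimulationTrace(
        model=Model.SW,
        times=np.array(times),
        states=np.array(states),
        com_x=np.array(com_x),
        com_y=np.array(com_y),
        grf_left=np.zeros(n),
        grf_right=np.zeros(n),
        phase=phases,
        events=ev_log,
        termination=termination,
        steps_completed=steps,
        state_names=SW_STATE_NAMES,
        meta={
            "strategy": cfg.strategy.value,
            "u": cfg.u,
            "k_f": params.k_f,
            "time_scale": params.time_scale,
            "length_scale": params.l,
        },
    )


def first_strike_angle(
    k_f: float,
    step_length: float = DEFAULT_STEP_LENGTH,
    theta_dot0: float = DEFAULT_THETA_DOT0,
    tolerances: Tolerances | None = None,
) -> float:
    """Stance angle at the first heel strike from the reference pose.

    Returns ``nan`` if the step fails before striking.
    """
    theta0 = math.asin(step_length / 2.0)
    params = SWParams(
        k_f=k_f, pushoff=periodic_pushoff(theta0, theta_dot0)
    )
    cfg = UnloadingConfig(strategy=Strategy.CF, u=0.0)
    init = sw_initial_state(step_length, theta_dot0)
    trace = simulate_sw(
        params, cfg, init, step_budget=1, tolerances=tolerances or Tolerances()
    )
    if trace.steps_completed < 1:
        return math.nan
    # post-impact theta equals -theta_minus of the strike
    return -float(trace.states[-1][0])  # = theta_minus (negative for a forward step)


def calibrate_default_gait(
    step_length: float = DEFAULT_STEP_LENGTH,
    theta_dot0: float = DEFAULT_THETA_DOT0,
    k_f_bracket: tuple[float, float] = (1.0, 2.5),
    tol: float = 1e-10,
) -> dict[str, float]:
    """Calibrate the hip spring for a limit cycle at the given step length.

    On the symmetric cycle the toe-off magnitude follows analytically
    (``p = |theta_dot0| tan(theta0)``); the hip-spring stiffness is found
    by bisection so that the swing leg strikes exactly at the mirror angle
    ``-theta0``, closing the cycle.  The shipped ``SWParams`` defaults were
    produced by this routine at step length 0.7167.
    """
    theta0 = math.asin(step_length / 2.0)

    def resid(k_f: float) -> float:
        th = first_strike_angle(k_f, step_length, theta_dot0)
        if math.isnan(th):
            return math.inf
        return th + theta0  # strike at the mirror angle -theta0 closes the cycle

    lo, hi = k_f_bracket
    f_lo, f_hi = resid(lo), resid(hi)
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo * f_hi > 0:
        raise ValueError(
            f"k_f bracket {k_f_bracket} does not bracket a strike-angle root "
            f"(residuals {f_lo:.3g}, {f_hi:.3g})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = resid(mid)
        if not np.isfinite(f_mid):
            raise ValueError(f"step failed during bisection at k_f={mid}")
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    k_f = 0.5 * (lo + hi)
    return {
        "k_f": k_f,
        "pushoff": periodic_pushoff(theta0, theta_dot0),
        "theta_dot0": theta_dot0,
        "residual": resid(k_f),
    }
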