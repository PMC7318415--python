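"""Bipedal walking SLIP (spring-loaded inverted pendulum) under body-weight support.

A point mass on two massless linear leg springs.  The stride cycles through
single-limb stance (SLS) on one leg, double-limb stance (DLS) after the
swing leg touches down at a fixed angle of attack, and SLS on the other leg
after the trailing spring returns to its rest length.  Touchdown occurs
when the COM height falls through ``l0 sin(alpha)``; the landing foot is
placed ``l0 cos(alpha)`` ahead of the COM.

Spring coefficients follow the usual radial-stiffness form
``P = k (l0 / l_leg - 1)``; the vertical ground reaction force of a leg is
``P * y_c``.  The unloading force is vertical and only the vertical
equation of motion changes with the strategy; at ``u = 0`` all strategies
reduce to the unsupported model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from .config import (
    FailureThresholds,
    Model,
    SLIPParams,
    Strategy,
    Tolerances,
    UnloadingConfig,
)
from .trace import Event, EventKind, SimulationTrace, Termination

SLIP_STATE_NAMES = ("x_c", "y_c", "vx", "vy")

#: reference initial forward speed (m/s) of the walking gait
DEFAULT_SPEED = 1.1185


def leg_force_coeff(x: float, y: float, fp: float, p: SLIPParams) -> float:
    """Radial spring coefficient ``k (l0 / l_leg - 1)`` for a leg at ``fp``.

    The leg spring is unilateral: it pushes while compressed and exerts no
    force beyond its rest length (a leg cannot pull on the ground), so the
    coefficient is clamped at zero for ``l_leg >= l0``.  The foot stays
    attached until its phase-transition event fires.
    """
    l_leg = math.hypot(x - fp, y)
    if l_leg == 0.0:
        raise ZeroDivisionError("leg length is zero: spring force singular")
    return max(p.k * (p.l0 / l_leg - 1.0), 0.0)


def effective_gravity(p: SLIPParams, cfg: UnloadingConfig) -> float:
    """Reduced vertical gravity for the CF and CW strategies.

    CF: ``(1 - u) g``; CW: ``(1 - u)/(1 + u) g`` (the counterweight's
    inertia opposes the attachment-point acceleration).  TS keeps full
    gravity and adds the explicit spring force instead.
    """
    if cfg.strategy is Strategy.CF:
        return (1.0 - cfg.u) * p.g
    if cfg.strategy is Strategy.CW:
        return (1.0 - cfg.u) / (1.0 + cfg.u) * p.g
    return p.g


def ts_force(y: float, p: SLIPParams, cfg: UnloadingConfig) -> float:
    """Tuned-spring unloading force ``k_s (y_c0 - y_c + dl0)`` (signed)."""
    if cfg.u == 0.0:
        return 0.0
    cfg.require_ts()
    return cfg.k_s * (cfg.y_c0 - y + cfg.delta_l0)


def slip_derivatives(
    s: np.ndarray,
    p: SLIPParams,
    cfg: UnloadingConfig,
    feet: tuple[float, ...],
) -> np.ndarray:
    """COM acceleration for the active feet (1 foot: SLS, 2 feet: DLS)."""
    x, y, vx, vy = s
    ax = 0.0
    ay_spring = 0.0
    for fp in feet:
        c = leg_force_coeff(x, y, fp, p)
        ax += c * (x - fp) / p.m
        ay_spring += c * y / p.m
    if cfg.strategy is Strategy.TS:
        ay = ay_spring - p.g + ts_force(y, p, cfg) / p.m
    else:
        ay = ay_spring - effective_gravity(p, cfg)
    return np.array([vx, vy, ax, ay])


def slip_initial_state(speed: float = DEFAULT_SPEED, p: SLIPParams | None = None) -> np.ndarray:
    """Standing start: COM atop an uncompressed vertical stance leg.

    The walker starts in single-limb stance at the apex (``y = l0``,
    ``vy = 0``) with forward speed ``speed``; the stance foot is directly
    below the COM.
    """
    p = p or SLIPParams()
    if speed <= 0:
        raise ValueError(f"speed={speed} must be > 0")
    return np.array([0.0, p.l0, speed, 0.0])


def touchdown_height(p: SLIPParams) -> float:
    return p.l0 * math.sin(p.alpha)


def simulate_slip(
    params: SLIPParams,
    cfg: UnloadingConfig,
    init: np.ndarray,
    step_budget: int = 20,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
) -> SimulationTrace:
    """Hybrid event-driven integration of the bipedal walking SLIP.

    Each touchdown counts as one step.  Terminates at the step budget or on
    a failure predicate: the COM dropping below ``0.2 l0`` (fall), forward
    speed reaching zero (backward motion), or all loaded legs reaching
    their rest length (flight).
    """
    if step_budget < 1:
        raise ValueError(f"step_budget={step_budget} must be >= 1")
    tolerances = tolerances or Tolerances()
    failure = failure or FailureThresholds()

    state = np.asarray(init, dtype=float)
    if state.shape != (4,) or not np.all(np.isfinite(state)):
        raise ValueError("init must be a finite state [x_c, y_c, vx, vy]")

    y_td = touchdown_height(params)
    legs = ("left", "right")
    stance_idx = 0          # leg owning the (single) stance foot
    fp_trailing = float(state[0])  # foot directly below the COM at start
    fp_leading: float | None = None
    phase = "SLS"

    t = 0.0
    times = [t]
    states = [state.copy()]
    grf = {"left": [0.0], "right": [0.0]}
    grf[legs[stance_idx]][0] = max(
        leg_force_coeff(state[0], state[1], fp_trailing, params) * state[1], 0.0
    )
    phases = [phase]
    fp_t_series: list[float] = [fp_trailing]
    fp_l_series: list[float] = [math.nan]
    ev_log: list[Event] = []
    steps = 0
    termination = None

    def record(ts, ys, current_feet):
        fpt = current_feet.get(legs[stance_idx], math.nan)
        fpl_vals = [v for k, v in current_feet.items() if k != legs[stance_idx]]
        fpl = fpl_vals[0] if fpl_vals else math.nan
        for ti, yi in zip(ts, ys):
            times.append(ti)
            states.append(yi.copy())
            fp_t_series.append(fpt)
            fp_l_series.append(fpl)
            gl = gr = 0.0
            for leg_name, fp in current_feet.items():
                # vertical GRF of a loaded leg; clamp roundoff at the
                # rest-length boundary
                f = max(leg_force_coeff(yi[0], yi[1], fp, params) * yi[1], 0.0)
                if leg_name == "left":
                    gl = f
                else:
                    gr = f
            grf["left"].append(gl)
            grf["right"].append(gr)
            phases.append(phase)

    while steps < step_budget:
        if phase == "SLS":
            feet = (fp_trailing,)
            current_feet = {legs[stance_idx]: fp_trailing}
        else:
            feet = (fp_trailing, fp_leading)
            current_feet = {
                legs[stance_idx]: fp_trailing,
                legs[1 - stance_idx]: fp_leading,
            }

        def rhs(t_, y_):
            return slip_derivatives(y_, params, cfg, feet)

        evs = []

        def ev_fall(t_, y_):
            return y_[1] - failure.slip_min_height_frac * params.l0

        ev_fall.terminal, ev_fall.direction = True, -1.0

        def ev_backward(t_, y_):
            return y_[2]

        ev_backward.terminal, ev_backward.direction = True, -1.0

        if phase == "SLS":
            # the stance foot stays attached (at zero force if the spring
            # is at full length) until the swing leg touches down
            def ev_touchdown(t_, y_):
                return y_[1] - y_td

            ev_touchdown.terminal, ev_touchdown.direction = True, -1.0
            evs = [ev_touchdown, ev_fall, ev_backward]
        else:

            def ev_takeoff(t_, y_):
                return math.hypot(y_[0] - fp_trailing, y_[1]) - params.l0

            ev_takeoff.terminal, ev_takeoff.direction = True, 1.0
            evs = [ev_takeoff, ev_fall, ev_backward]

        sol = solve_ivp(
            rhs,
            (t, t + failure.max_step_time),
            state,
            method="RK45",
            rtol=tolerances.rtol,
            atol=tolerances.atol,
            max_step=tolerances.max_step,
            events=evs,
        )
        if not sol.success:
            termination = Termination.INTEGRATION_FAILURE
            break

        record(sol.t[1:], list(sol.y[:, 1:].T), current_feet)

        if sol.status != 1:
            termination = Termination.INTEGRATION_FAILURE
            t, state = sol.t[-1], sol.y[:, -1]
            break

        hit = [(te[0], i) for i, te in enumerate(sol.t_events) if len(te)]
        t_ev, which = min(hit)
        y_ev = sol.y_events[which][0]
        t, state = t_ev, y_ev.copy()

        if phase == "SLS":
            if which == 0:  # touchdown: place the leading foot at the angle of attack
                fp_leading = state[0] + params.l0 * math.cos(params.alpha)
                phase = "DLS"
                steps += 1
                ev_log.append(Event(t, EventKind.TOUCHDOWN, legs[1 - stance_idx]))
                record([t], [state], {
                    legs[stance_idx]: fp_trailing,
                    legs[1 - stance_idx]: fp_leading,
                })
                continue
            termination = (
                Termination.FELL if which == 1 else Termination.MOVED_BACKWARD
            )
            break
        else:
            if which == 0:  # trailing takeoff: single stance on the leading leg
                lead_len = math.hypot(state[0] - fp_leading, state[1])
                if lead_len >= params.l0 - 1e-9:
                    # both legs unloaded at the same instant: airborne
                    termination = Termination.TOOK_FLIGHT
                    break
                ev_log.append(Event(t, EventKind.TAKEOFF, legs[stance_idx]))
                stance_idx = 1 - stance_idx
                fp_trailing = fp_leading
                fp_leading = None
                phase = "SLS"
                record([t], [state], {legs[stance_idx]: fp_trailing})
                continue
            termination = (
                Termination.FELL if which == 1 else Termination.MOVED_BACKWARD
            )
            break

    if termination is None:
        termination = Termination.STEP_BUDGET_REACHED

    return SimulationTrace(
        model=Model.SLIP,
        times=np.array(times),
        states=np.array(states),
        com_x=np.array([s_[0] for s_ in states]),
        com_y=np.array([s_[1] for s_ in states]),
        grf_left=np.array(grf["left"]),
        grf_right=np.array(grf["right"]),
        phase=phases,
        events=ev_log,
        termination=termination,
        steps_completed=steps,
        state_names=SLIP_STATE_NAMES,
        meta={
            "strategy": cfg.strategy.value,
            "u": cfg.u,
            "time_scale": 1.0,
            "length_scale": 1.0,
            "fp_trailing": np.array(fp_t_series),
            "fp_leading": np.array(fp_l_series),
        },
    )
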