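"""Model dispatch and tuned-spring baseline preparation.

The tuned-spring strategy needs the walker's unsupported cadence: before a
TS run, the same model and initial condition are simulated at 0 % BWS, the
cadence is extracted (five strides averaged after the transient), and the
spring is tuned to ``omega = 2 pi c``.  Baselines are cached per (model,
parameters, initial condition).
"""

from __future__ import annotations

import math

import numpy as np

from .config import (
    FailureThresholds,
    Model,
    SLIPParams,
    Strategy,
    SWParams,
    Tolerances,
    UnloadingConfig,
)
from .metrics import extract_gait_parameters
from .simplest_walker import simulate_sw
from .slip import simulate_slip
from .trace import SimulationTrace, Termination
from .unloading import estimate_yc0, tune_spring


def simulate(
    model: Model | str,
    params: SWParams | SLIPParams,
    cfg: UnloadingConfig,
    init: np.ndarray,
    step_budget: int = 20,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
) -> SimulationTrace:
    """Run a hybrid gait simulation of either walker."""
    model = Model(model)
    if model is Model.SW:
        if not isinstance(params, SWParams):
            raise TypeError("SW model requires SWParams")
        return simulate_sw(params, cfg, init, step_budget, tolerances, failure)
    if not isinstance(params, SLIPParams):
        raise TypeError("SLIP model requires SLIPParams")
    return simulate_slip(params, cfg, init, step_budget, tolerances, failure)


class BaselineError(RuntimeError):
    """The 0 %-BWS baseline run cannot provide a cadence."""


def baseline_cadence(
    model: Model | str,
    params: SWParams | SLIPParams,
    init: np.ndarray,
    step_budget: int = 20,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
) -> float:
    """Cadence (steps/s, real time) of the unsupported walker.

    Runs the model at 0 % BWS from ``init`` and averages at least five
    strides after discarding the transient.
    """
    return baseline_gait_reference(
        model, params, init, step_budget, tolerances, failure
    )[0]


def baseline_gait_reference(
    model: Model | str,
    params: SWParams | SLIPParams,
    init: np.ndarray,
    step_budget: int = 20,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
) -> tuple[float, float, float]:
    """Baseline gait reference quantities from the 0 %-BWS run.

    Returns ``(cadence, y_mean, y_lowpass)``: the cadence (steps/s), the
    time-averaged COM height (m) over the trace's steady part, and the
    heavy low-pass estimate of the reference height (floored at the mean).
    The tuned spring's reference position ``y_c0`` is defined as the
    average attachment position during unsupported walking.
    """
    cfg0 = UnloadingConfig(strategy=Strategy.CF, u=0.0)
    trace = simulate(model, params, cfg0, init, step_budget, tolerances, failure)
    if trace.termination is not Termination.STEP_BUDGET_REACHED:
        raise BaselineError(
            f"0% BWS baseline failed after {trace.steps_completed} steps "
            f"({trace.termination.value}); cannot tune the spring"
        )
    gp = extract_gait_parameters(trace)
    tscale = trace.meta.get("time_scale", 1.0)
    lscale = trace.meta.get("length_scale", 1.0)
    # time-average over the trace's second half (past the transient)
    t, y = trace.times * tscale, trace.com_y * lscale
    half = t >= t[-1] / 2.0
    y_mean = float(np.trapezoid(y[half], t[half]) / (t[half][-1] - t[half][0]))
    dt = 0.01
    grid = np.arange(t[0], t[-1], dt)
    y_lp = estimate_yc0(np.interp(grid, t, y), dt, floor_value=y_mean)
    return gp.cadence, y_mean, y_lp


class UnloadingFactory:
    """Build :class:`UnloadingConfig` objects, tuning TS springs on demand.

    Caches the baseline cadence per (model, params, init) so that TS sweeps
    recompute ``omega`` only from the 0 % run of the same initial condition.
    """

    def __init__(
        self,
        model: Model | str,
        params: SWParams | SLIPParams,
        tolerances: Tolerances | None = None,
        failure: FailureThresholds | None = None,
        baseline_step_budget: int = 20,
    ):
        self.model = Model(model)
        self.params = params
        self.tolerances = tolerances
        self.failure = failure
        self.baseline_step_budget = baseline_step_budget
        self._baseline_cache: dict[tuple, tuple[float, float, float]] = {}

    def _key(self, init: np.ndarray) -> tuple:
        return tuple(np.asarray(init, dtype=float).tolist())

    def baseline(self, init: np.ndarray) -> tuple[float, float, float]:
        """(cadence, mean height, low-pass height) of the 0 % run from ``init``."""
        key = self._key(init)
        if key not in self._baseline_cache:
            self._baseline_cache[key] = baseline_gait_reference(
                self.model,
                self.params,
                init,
                self.baseline_step_budget,
                self.tolerances,
                self.failure,
            )
        return self._baseline_cache[key]

    def cadence(self, init: np.ndarray) -> float:
        return self.baseline(init)[0]

    def unloading(
        self,
        strategy: Strategy | str,
        u: float,
        init: np.ndarray,
        y_c0_mode: str = "baseline_mean",
    ) -> UnloadingConfig:
        """Config for a strategy at unloading fraction ``u`` from pose ``init``.

        For TS, the spring reference height ``y_c0`` is by default the mean
        attachment height during the 0 % baseline walk (its defined average
        position); ``y_c0_mode="initial_pose"`` uses the starting pose
        instead.  The SW model's equations of motion carry the upright pose
        as reference by construction, so the mode only affects the SLIP
        model.
        """
        strategy = Strategy(strategy)
        if strategy is not Strategy.TS or u == 0.0:
            return UnloadingConfig(strategy=strategy, u=u)
        c, y_mean, y_lp = self.baseline(init)
        if self.model is Model.SW:
            m, g = self.params.M, self.params.g
            y_c0 = self.params.l  # Eqs. use y_c = l cos(theta) about upright
        elif y_c0_mode == "baseline_mean":
            m, g = self.params.m, self.params.g
            y_c0 = y_mean
        elif y_c0_mode == "lowpass_filtered":
            m, g = self.params.m, self.params.g
            y_c0 = y_lp
        else:
            m, g = self.params.m, self.params.g
            y_c0 = float(init[1])
        k_s, delta_l0, omega = tune_spring(u, m, c, g)
        return UnloadingConfig(
            strategy=Strategy.TS,
            u=u,
            k_s=k_s,
            delta_l0=delta_l0,
            omega=omega,
            y_c0=y_c0,
            y_c0_mode=y_c0_mode,
        )
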