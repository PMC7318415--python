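"""Feasibility sweeps, initial-condition sensitivity grids, and the benchmark.

The feasibility protocol: simulate each strategy at BWS levels 0-100 % in
5 % increments; a level is feasible when the walker completes at least 20
steps.  The highest feasible level is the maximum feasible BWS
(``beta_max``).  The benchmark assembles per-parameter trend vectors up to
``beta_max``, modela-w per level, the loss of dynamic similarity
(``delta_gd``) per model and strategy, and — for the constant-force
strategy — the RMS error against a normalised human reference trend
(``mrmse``) per parameter and environment.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    FailureThresholds,
    Model,
    SLIPParams,
    Strategy,
    SWParams,
    Tolerances,
)
from .metrics import (
    DELTA_GD_LEVELS,
    MRMSE_LEVELS,
    SLIP_PARAMETERS,
    SW_PARAMETERS,
    GaitParameters,
    InsufficientStridesError,
    TrendVector,
    delta_gd,
    extract_gait_parameters,
    modela_w,
    mrmse,
)
from .reference import HumanReference
from .simulate import BaselineError, UnloadingFactory, simulate
from .simplest_walker import sw_initial_state
from .slip import slip_initial_state
from .trace import FLOAT_FMT, Termination

log = logging.getLogger(__name__)

FULL_LEVELS = tuple(range(0, 105, 5))
FEASIBLE_MIN_STEPS = 20


@dataclass
class LevelResult:
    level: int                    # percent BWS
    feasible: bool
    steps_completed: int
    termination: str
    avg_speed: float              # m/s, nan if too short to average
    gait: GaitParameters | None


@dataclass
class SweepResult:
    """Feasibility sweep of one model x strategy x initial condition."""

    model: Model
    strategy: Strategy
    init_descriptor: float        # initial speed (SLIP, m/s) or step length (SW, m)
    levels_tested: tuple[int, ...]
    per_level: dict[int, LevelResult] = field(default_factory=dict)

    @property
    def feasible(self) -> dict[int, bool]:
        return {lvl: r.feasible for lvl, r in self.per_level.items()}

    @property
    def beta_max(self) -> int:
        """Highest feasible level; -1 when no level is feasible."""
        feas = [lvl for lvl, r in self.per_level.items() if r.feasible]
        return max(feas) if feas else -1

    @property
    def beta_min(self) -> int:
        feas = [lvl for lvl, r in self.per_level.items() if r.feasible]
        return min(feas) if feas else -1


def make_initial_state(model: Model, init_value: float, params) -> np.ndarray:
    """Initial state from the scalar initial-condition descriptor.

    SLIP: initial forward speed (m/s); SW: initial step length (in units of
    the leg length).
    """
    if model is Model.SW:
        return sw_initial_state(step_length=init_value / params.l)
    return slip_initial_state(speed=init_value, p=params)


def find_beta_max(
    model: Model | str,
    params: SWParams | SLIPParams,
    strategy: Strategy | str,
    init_value: float,
    step_budget: int = FEASIBLE_MIN_STEPS,
    levels: tuple[int, ...] = FULL_LEVELS,
    exhaustive: bool = True,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
    collect_gait: bool = False,
) -> SweepResult:
    """Sweep BWS levels and find the maximum feasible unloading.

    A level is feasible when the walker completes ``step_budget`` (>= 20)
    steps.  With ``exhaustive=False``, levels beyond three consecutive
    infeasible ones are skipped (feasibility at higher levels need not be
    contiguous, so exhaustive mode is the default for reported results).
    When ``collect_gait`` is set, stride-averaged gait parameters are
    extracted from each feasible level's trace.
    """
    model = Model(model)
    strategy = Strategy(strategy)
    factory = UnloadingFactory(model, params, tolerances, failure, step_budget)
    init = make_initial_state(model, init_value, params)

    result = SweepResult(model, strategy, init_value, tuple(levels))
    consecutive_infeasible = 0
    for lvl in levels:
        if not exhaustive and consecutive_infeasible >= 3:
            result.per_level[lvl] = LevelResult(
                lvl, False, 0, "skipped", math.nan, None
            )
            continue
        u = lvl / 100.0
        try:
            cfg = factory.unloading(strategy, u, init)
        except BaselineError as e:
            log.warning("level %d%%: %s", lvl, e)
            result.per_level[lvl] = LevelResult(
                lvl, False, 0, "baseline_infeasible", math.nan, None
            )
            consecutive_infeasible += 1
            continue
        trace = simulate(model, params, cfg, init, step_budget, tolerances, failure)
        feasible = (
            trace.termination is Termination.STEP_BUDGET_REACHED
            and trace.steps_completed >= step_budget
        )
        gait = None
        speed = math.nan
        if feasible:
            try:
                gait = extract_gait_parameters(trace)
                speed = gait.walking_speed
            except InsufficientStridesError:
                gait = None
        if not collect_gait:
            gait = None
        result.per_level[lvl] = LevelResult(
            lvl, feasible, trace.steps_completed, trace.termination.value, speed, gait
        )
        consecutive_infeasible = 0 if feasible else consecutive_infeasible + 1
    if result.beta_max < 0:
        log.warning(
            "%s/%s at init %.4f: no feasible BWS level",
            model.value,
            strategy.value,
            init_value,
        )
    return result


def sensitivity_grid(
    model: Model | str,
    params: SWParams | SLIPParams,
    strategy: Strategy | str,
    init_values: list[float],
    levels: tuple[int, ...] = FULL_LEVELS,
    step_budget: int = FEASIBLE_MIN_STEPS,
    exhaustive: bool = False,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
) -> pd.DataFrame:
    """Feasibility and average speed over an initial-condition grid.

    Returns a tidy frame (init_value, level, feasible, avg_speed) suitable
    for heat-map rendering; integration failures count as infeasible.
    """
    if not init_values:
        raise ValueError("init_values must be non-empty")
    rows = []
    for iv in init_values:
        sweep = find_beta_max(
            model,
            params,
            strategy,
            iv,
            step_budget,
            levels,
            exhaustive,
            tolerances,
            failure,
        )
        for lvl in levels:
            r = sweep.per_level[lvl]
            rows.append(
                {
                    "init_value": iv,
                    "level": lvl,
                    "feasible": r.feasible,
                    "avg_speed": r.avg_speed,
                }
            )
    return pd.DataFrame(rows)


def default_init_grid(model: Model) -> list[float]:
    """The 15-value initial-condition grids of the sensitivity protocol."""
    if Model(model) is Model.SLIP:
        return [round(v, 4) for v in np.linspace(0.6185, 1.6185, 15)]
    return [round(v, 4) for v in np.linspace(0.2167, 1.2167, 15)]


def select_init(sweeps: dict[float, SweepResult], original: float) -> float:
    """Pick the analysis initial condition from a grid of sweeps.

    Among initial conditions tied on the highest ``beta_max``, picks the
    one nearest the original value (tie-break: smaller absolute difference,
    then smaller init).
    """
    best = max(s.beta_max for s in sweeps.values())
    tied = [iv for iv, s in sweeps.items() if s.beta_max == best]
    tied.sort(key=lambda iv: (abs(iv - original), iv))
    return tied[0]


ORIGINAL_INIT = {Model.SLIP: 1.1185, Model.SW: 0.7167}


@dataclass
class BenchmarkReport:
    """Trend vectors and similarity statistics for all model x strategy cells."""

    trends: dict[tuple[str, str, str], TrendVector]       # (model, strategy, parameter)
    modela_w: dict[tuple[str, str], dict[int, float]]     # (model, strategy) -> level -> value
    delta_gd: dict[tuple[str, str], float]                # (model, strategy)
    mrmse: dict[tuple[str, str, str], float]              # (model, parameter, environment); CF only
    beta_max: dict[tuple[str, str], int]                  # (model, strategy)
    config: dict = field(default_factory=dict)

    def trends_frame(self) -> pd.DataFrame:
        rows = []
        for (model, strategy, parameter), tv in sorted(self.trends.items()):
            for lvl, raw, norm, feas in zip(
                tv.levels, tv.values, tv.normalized, tv.feasible
            ):
                rows.append(
                    {
                        "model": model,
                        "strategy": strategy,
                        "parameter": parameter,
                        "bws_level": lvl,
                        "raw": raw,
                        "normalized": norm,
                        "feasible": bool(feas),
                    }
                )
        return pd.DataFrame(rows)

    def modela_w_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "strategy": s, "bws_level": lvl, "modela_w": v}
            for (m, s), series in sorted(self.modela_w.items())
            for lvl, v in sorted(series.items())
        ]
        return pd.DataFrame(rows)

    def delta_gd_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "strategy": s, "delta_gd_percent": v}
            for (m, s), v in sorted(self.delta_gd.items())
        ]
        return pd.DataFrame(rows)

    def mrmse_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "strategy": Strategy.CF.value,
                "parameter": p,
                "environment": env,
                "mrmse_percent": v,
            }
            for (m, p, env), v in sorted(self.mrmse.items())
        ]
        return pd.DataFrame(rows)

    def beta_max_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "strategy": s, "beta_max": v}
            for (m, s), v in sorted(self.beta_max.items())
        ]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Write the report bundle as tidy CSVs plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = {
            "trends.csv": self.trends_frame(),
            "modela_w.csv": self.modela_w_frame(),
            "delta_gd.csv": self.delta_gd_frame(),
            "mrmse.csv": self.mrmse_frame(),
            "beta_max.csv": self.beta_max_frame(),
        }
        for name, df in frames.items():
            df.to_csv(outdir / name, index=False, float_format=FLOAT_FMT)
        manifest = {"config": self.config, "files": sorted(frames)}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )


def run_benchmark(
    reference: HumanReference | None = None,
    models: tuple[Model, ...] = (Model.SW, Model.SLIP),
    strategies: tuple[Strategy, ...] = (Strategy.CF, Strategy.CW, Strategy.TS),
    init_values: dict[Model, float] | None = None,
    step_budget: int = FEASIBLE_MIN_STEPS,
    sw_params: SWParams | None = None,
    slip_params: SLIPParams | None = None,
    tolerances: Tolerances | None = None,
    failure: FailureThresholds | None = None,
    mrmse_denominator: int | None = None,
) -> BenchmarkReport:
    """The full protocol: sweeps, trends, modela-w, delta-gd and mrmse.

    Deterministic given its configuration.  ``reference`` supplies the
    normalised human trends for the mrmse stage (constant-force strategy
    only); a missing reference parameter is reported as absent, not zero.
    """
    init_values = init_values or dict(ORIGINAL_INIT)
    params_by_model = {
        Model.SW: sw_params or SWParams(),
        Model.SLIP: slip_params or SLIPParams(),
    }

    trends: dict[tuple[str, str, str], TrendVector] = {}
    mw_all: dict[tuple[str, str], dict[int, float]] = {}
    dgd_all: dict[tuple[str, str], float] = {}
    mrmse_all: dict[tuple[str, str, str], float] = {}
    beta_all: dict[tuple[str, str], int] = {}

    for model in models:
        params = params_by_model[Model(model)]
        parameters = SW_PARAMETERS if Model(model) is Model.SW else SLIP_PARAMETERS
        leg_length = params.l if Model(model) is Model.SW else params.l0
        for strategy in strategies:
            sweep = find_beta_max(
                model,
                params,
                strategy,
                init_values[Model(model)],
                step_budget,
                tolerances=tolerances,
                failure=failure,
                collect_gait=True,
            )
            key = (Model(model).value, Strategy(strategy).value)
            beta_all[key] = sweep.beta_max

            bmax = max(sweep.beta_max, 0)
            levels = tuple(range(0, bmax + 5, 5))
            feas = np.array(
                [sweep.per_level[lvl].feasible and sweep.per_level[lvl].gait is not None
                 for lvl in levels]
            )
            for parameter in parameters:
                vals = np.array(
                    [
                        sweep.per_level[lvl].gait.value(parameter)
                        if feas[i]
                        else math.nan
                        for i, lvl in enumerate(levels)
                    ]
                )
                trends[key + (parameter,)] = TrendVector(parameter, levels, vals, feas)

            # modela-w per feasible level and the dynamic-similarity loss
            mw = {}
            for i, lvl in enumerate(levels):
                if not feas[i]:
                    continue
                g_ = sweep.per_level[lvl].gait
                mw[lvl] = modela_w(g_.walking_speed, g_.cadence, leg_length, params.g)
            mw_all[key] = mw
            if 0 in mw:
                series = [mw[lvl] for lvl in DELTA_GD_LEVELS if lvl in mw]
                if series:
                    dgd_all[key] = delta_gd(np.array(series), mw[0])
                else:
                    dgd_all[key] = math.nan
            else:
                dgd_all[key] = math.nan

            # mrmse against the human reference: CF only
            if reference is not None and Strategy(strategy) is Strategy.CF:
                for parameter in parameters:
                    tv = trends[key + (parameter,)]
                    p_n = _trend_at_levels(tv, MRMSE_LEVELS)
                    for env in reference.environments(parameter):
                        p_h = reference.means(parameter, env, MRMSE_LEVELS)
                        if p_h is None:
                            continue
                        mrmse_all[(key[0], parameter, env)] = mrmse(
                            p_n, p_h, mrmse_denominator
                        )

    return BenchmarkReport(
        trends=trends,
        modela_w=mw_all,
        delta_gd=dgd_all,
        mrmse=mrmse_all,
        beta_max=beta_all,
        config={
            "init_values": {m.value: v for m, v in init_values.items()},
            "step_budget": step_budget,
            "models": [Model(m).value for m in models],
            "strategies": [Strategy(s).value for s in strategies],
        },
    )


def _trend_at_levels(tv: TrendVector, levels: tuple[int, ...]) -> np.ndarray:
    """Normalised trend values at the requested levels; absent levels -> 0.

    Levels above ``beta_max`` are infeasible by definition and carry the
    penalised value zero.
    """
    by_level = dict(zip(tv.levels, tv.normalized))
    return np.array([by_level.get(lvl, 0.0) for lvl in levels])
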