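"""Domain types and configuration for body-weight-supported gait simulation.

Conventions
-----------
* ``u`` is the unloading fraction (0..1); body-weight-support levels are
  reported externally as integer percentages ``beta = 100 u``.
* The Simplest Walker (SW) is integrated in dimensionless units: lengths in
  units of the leg length ``l`` and time in units of ``sqrt(l/g)``.  The SLIP
  model is integrated in SI units.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any


class Strategy(str, enum.Enum):
    """Body-weight-support strategy."""

    CF = "cf"  # constant force: F = u m g
    CW = "cw"  # counterweight: F = u m (g - y_c'')
    TS = "ts"  # tuned spring:  F = k_s (y_c0 - y_c + dl0)


class Model(str, enum.Enum):
    SW = "sw"
    SLIP = "slip"


class ConfigError(ValueError):
    """Raised when a configuration violates its contract.

    Carries the full list of violations, not only the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class UnloadingConfig:
    """Unloading strategy, fraction, and tuned-spring parameters.

    For the TS strategy, ``k_s`` (N/m), ``delta_l0`` (m) and ``omega``
    (rad/s) are normally produced by :func:`bwsim.unloading.tune_spring`
    from the 0 %-BWS baseline cadence; ``y_c0`` is the reference height of
    the attachment point (default: the initial pose).
    """

    strategy: Strategy = Strategy.CF
    u: float = 0.0
    k_s: float | None = None
    delta_l0: float | None = None
    omega: float | None = None
    y_c0: float | None = None
    y_c0_mode: str = "baseline_mean"  # or "initial_pose" / "lowpass_filtered"

    def __post_init__(self) -> None:
        self.strategy = Strategy(self.strategy)
        errs = []
        if not (0.0 <= self.u <= 1.0):
            errs.append(f"u={self.u} outside [0, 1]")
        if self.y_c0_mode not in ("baseline_mean", "initial_pose", "lowpass_filtered"):
            errs.append(f"y_c0_mode={self.y_c0_mode!r} unknown")
        if errs:
            raise ConfigError(errs)

    def require_ts(self) -> None:
        """Validate that the tuned-spring parameters are set."""
        if self.strategy is not Strategy.TS:
            return
        errs = []
        for name in ("k_s", "delta_l0", "omega", "y_c0"):
            if getattr(self, name) is None:
                errs.append(f"TS strategy requires {name}")
        if errs:
            raise ConfigError(errs)


@dataclass
class SWParams:
    """Simplest Walker parameters.

    The walker is a point hip mass ``M`` on two massless legs of length
    ``l``; the foot-to-hip mass ratio is exactly zero in the equations of
    motion.  ``k_f`` is the dimensionless torsional hip-spring stiffness
    driving the swing leg; ``pushoff`` is the dimensionless impulsive
    toe-off magnitude (units of ``M sqrt(g l)``) applied along the trailing
    leg at heel strike, which restores the energy the inelastic collision
    dissipates — without it no level-ground limit cycle exists.  ``l``,
    ``g`` and ``M`` only set the physical scale when converting to SI
    units.
    """

    k_f: float = 1.0626392482014353  # calibrated: stable limit cycle at step length 0.7167
    pushoff: float = 0.1688904692855088  # toe-off impulse sustaining the cycle
    l: float = 1.0
    g: float = 9.81
    M: float = 80.0

    def __post_init__(self) -> None:
        errs = []
        if self.k_f < 0:
            errs.append(f"k_f={self.k_f} must be >= 0")
        if self.pushoff < 0:
            errs.append(f"pushoff={self.pushoff} must be >= 0")
        if self.l <= 0:
            errs.append(f"l={self.l} must be > 0")
        if self.g <= 0:
            errs.append(f"g={self.g} must be > 0")
        if self.M <= 0:
            errs.append(f"M={self.M} must be > 0")
        if errs:
            raise ConfigError(errs)

    @property
    def time_scale(self) -> float:
        """Seconds per dimensionless time unit, sqrt(l/g)."""
        return math.sqrt(self.l / self.g)


@dataclass
class SLIPParams:
    """Bipedal walking SLIP parameters (SI units).

    Point mass ``m`` on massless linear leg springs of rest length ``l0``
    and stiffness ``k``; the swing leg is placed at a fixed angle of attack
    ``alpha`` (measured from the ground, radians).
    """

    m: float = 80.0
    l0: float = 1.0
    k: float = 14000.0
    alpha: float = math.radians(69.0)
    g: float = 9.81

    def __post_init__(self) -> None:
        errs = []
        for name in ("m", "l0", "k", "g"):
            if getattr(self, name) <= 0:
                errs.append(f"{name}={getattr(self, name)} must be > 0")
        if not (0.0 < self.alpha < math.pi / 2):
            errs.append(f"alpha={self.alpha} outside (0, pi/2)")
        if errs:
            raise ConfigError(errs)


@dataclass
class FailureThresholds:
    """Predicates deciding when a simulated gait has failed.

    SW thresholds are dimensionless; SLIP thresholds are fractions of
    ``l0`` / absolute speeds.
    """

    sw_min_cos_theta: float = 0.5      # hip collapse: cos(theta) <= this
    sw_heelstrike_theta_min: float = 1e-3  # guard against the phi=2*theta double root
    slip_min_height_frac: float = 0.2  # fall: y_c <= frac * l0
    max_step_time: float = 10.0        # no event within this horizon -> failure

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class Tolerances:
    """Integrator tolerances; feasibility sweeps are sensitive to drift."""

    rtol: float = 1e-9
    atol: float = 1e-12
    max_step: float = math.inf


@dataclass
class SimulationConfig:
    """A complete, validated simulation request (JSON-serialisable)."""

    model: Model = Model.SLIP
    strategy: Strategy = Strategy.CF
    u: float = 0.0
    params: SWParams | SLIPParams = field(default_factory=SLIPParams)
    init: dict[str, float] = field(default_factory=dict)
    step_budget: int = 20
    tolerances: Tolerances = field(default_factory=Tolerances)
    failure: FailureThresholds = field(default_factory=FailureThresholds)
    seed: int = 0  # reserved; the dynamics are deterministic


def read_config(path: str | Path) -> SimulationConfig:
    """Read and validate a JSON simulation config.

    Collects *all* violations into a single :class:`ConfigError` rather than
    failing on the first.
    """
    raw = json.loads(Path(path).read_text())
    return parse_config(raw)


def parse_config(raw: dict[str, Any]) -> SimulationConfig:
    errs: list[str] = []

    model_name = raw.get("model", "slip")
    try:
        model = Model(model_name)
    except ValueError:
        errs.append(f"model={model_name!r} not one of {[m.value for m in Model]}")
        model = Model.SLIP

    strat_name = raw.get("strategy", "cf")
    try:
        strategy = Strategy(strat_name)
    except ValueError:
        errs.append(f"strategy={strat_name!r} not one of {[s.value for s in Strategy]}")
        strategy = Strategy.CF

    u = float(raw.get("u", 0.0))
    if not (0.0 <= u <= 1.0):
        errs.append(f"u={u} outside [0, 1]")

    step_budget = int(raw.get("step_budget", 20))
    if step_budget < 1:
        errs.append(f"step_budget={step_budget} must be >= 1")

    params_raw = dict(raw.get("params", {}))
    params: SWParams | SLIPParams
    try:
        params = SWParams(**params_raw) if model is Model.SW else SLIPParams(**params_raw)
    except ConfigError as e:
        errs.extend(e.errors)
        params = SWParams() if model is Model.SW else SLIPParams()
    except TypeError as e:
        errs.append(f"params: {e}")
        params = SWParams() if model is Model.SW else SLIPParams()

    tol = Tolerances(**raw.get("tolerances", {}))
    failure = FailureThresholds(**raw.get("failure", {}))

    if errs:
        raise ConfigError(errs)
    return SimulationConfig(
        model=model,
        strategy=strategy,
        u=u,
        params=params,
        init=dict(raw.get("init", {})),
        step_budget=step_budget,
        tolerances=tol,
        failure=failure,
        seed=int(raw.get("seed", 0)),
    )
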