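"""Body-weight-support force laws and tuned-spring design.

Three idealised unloading strategies applied as a purely vertical force at
the walker's centre of mass:

* constant force (CF):      F = u m g
* counterweight (CW):       F = u m (g - y_c''), the counterweight of mass
  u m mirrors the attachment point's vertical motion and adds its inertia;
* tuned spring (TS):        F = k_s (y_c0 - y_c + dl0), with the stiffness
  tuned to the walker's unsupported cadence so that, for near-harmonic
  vertical COM motion at that cadence, the spring compensates gravity *and*
  inertia of the unloaded mass simultaneously.

The forces are returned signed: a counterweight or spring can transiently
pull downward and no clamping is applied (ideal bidirectional rope/pulley).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .config import ConfigError, Strategy, UnloadingConfig

log = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


def unloading_force(
    cfg: UnloadingConfig,
    m: float,
    g: float,
    y_c: float = 0.0,
    y_c_ddot: float = 0.0,
) -> float:
    """Vertical (upward-positive) unloading force in newtons.

    Parameters
    ----------
    cfg : unloading strategy and parameters.
    m : supported mass (kg).
    g : gravity (m/s^2).
    y_c : attachment-point height (m); used by TS only.
    y_c_ddot : attachment-point vertical acceleration (m/s^2); CW only.
    """
    if cfg.strategy is Strategy.CF:
        return cfg.u * m * g
    if cfg.strategy is Strategy.CW:
        return cfg.u * m * (g - y_c_ddot)
    # tuned spring
    cfg.require_ts()
    f = cfg.k_s * (cfg.y_c0 - y_c + cfg.delta_l0)
    if f < 0.0:
        log.warning("tuned-spring unloading force is negative (%.3f N)", f)
    return f


def tune_spring(u: float, m: float, c: float, g: float = 9.81) -> tuple[float, float, float]:
    """Tune the elastic-support stiffness to the unsupported cadence.

    With ``omega = 2 pi c`` (``c`` the 0 %-BWS cadence in steps/s), the
    stiffness ``k_s = u m omega^2`` makes the spring's restoring force track
    the inertial force of the unloaded mass for harmonic COM motion at the
    cadence frequency, and the pretension ``dl0 = g / omega^2`` makes the
    static unloading equal ``u m g`` in the reference pose.  ``dl0`` is
    independent of both ``u`` and ``m``.

    Returns ``(k_s, delta_l0, omega)``.
    """
    if not (0.0 <= u <= 1.0):
        raise ConfigError([f"u={u} outside [0, 1]"])
    if m <= 0:
        raise ConfigError([f"m={m} must be > 0"])
    if c <= 0:
        raise ConfigError([f"cadence c={c} must be > 0"])
    omega = TWO_PI * c
    k_s = u * m * omega**2
    delta_l0 = g / omega**2
    return k_s, delta_l0, omega


def estimate_yc0(
    y_series: np.ndarray,
    dt: float,
    floor_value: float,
    rise_time: float = 15.0,
) -> float:
    """Reference attachment height from a heavy first-order low-pass filter.

    The filter's 10-90 % rise time is ``rise_time`` seconds (time constant
    ``rise_time / ln 81``, about ``rise_time / 2.2``).  The returned
    reference is the larger of the filter's final output and
    ``floor_value``.  The default mode for the SW and SLIP walkers uses the
    initial pose instead; this estimator is an opt-in alternative for
    signals whose initial height is unrepresentative.
    """
    y = np.asarray(y_series, dtype=float)
    if y.size == 0:
        raise ValueError("y_series must be non-empty")
    if dt <= 0:
        raise ValueError(f"dt={dt} must be > 0")
    tau = rise_time / math.log(81.0)  # 10-90% rise time of a 1st-order lag = tau ln 81
    a = math.exp(-dt / tau)
    state = 0.0
    for v in y:
        state = a * state + (1.0 - a) * v
    return max(state, floor_value)
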