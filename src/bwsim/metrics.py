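"""Stride-level gait parameters and trend/similarity statistics.

Extraction: spatio-temporal parameters (stride length, cadence, walking
speed, gait-phase fractions) and vertical-GRF peaks are averaged over at
least five strides after discarding an initial transient.

Comparison: per-parameter trends across body-weight-support levels are
normalised by their 0 %-BWS value; infeasible levels are penalised as zero.
Model trends are compared against a normalised human reference trend with
an RMS error (``mrmse``), and the loss of dynamic similarity across levels
is the RMS change in the dimensionless gait number modela-w (``delta_gd``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import Model
from .trace import EventKind, SimulationTrace

#: BWS levels (percent) entering the mrmse comparison
MRMSE_LEVELS = tuple(range(5, 45, 5))
#: BWS levels (percent) entering the delta-gd comparison
DELTA_GD_LEVELS = tuple(range(5, 40, 5))


class InsufficientStridesError(ValueError):
    """Trace too short for the requested stride averaging."""


@dataclass
class GaitParameters:
    """Stride-averaged gait parameters in SI units."""

    stride_length: float          # m
    cadence: float                # steps/s
    walking_speed: float          # m/s
    dls_fraction: float           # proportion of stride
    sls_fraction: float           # proportion of stride
    stance_fraction: float        # proportion of stride
    stance_duration: float        # s (per-leg stance time)
    vgrf_peak1: float             # N, weight-acceptance peak (nan for SW)
    vgrf_peak2: float             # N, push-off peak (nan for SW)
    n_strides_averaged: int
    degenerate_grf_shape: bool = False  # GRF profile lost its M-shape

    def value(self, parameter: str) -> float:
        return getattr(self, parameter)


#: trend parameters reported per model
SW_PARAMETERS = ("stride_length", "cadence", "walking_speed", "stance_duration")
SLIP_PARAMETERS = (
    "stride_length",
    "cadence",
    "walking_speed",
    "dls_fraction",
    "sls_fraction",
    "stance_fraction",
    "vgrf_peak1",
    "vgrf_peak2",
)


def extract_gait_parameters(
    trace: SimulationTrace,
    discard_strides: int = 3,
    min_strides: int = 5,
) -> GaitParameters:
    """Average gait parameters over complete strides of a trace.

    The first ``discard_strides`` strides are dropped as transient; at
    least ``min_strides`` complete strides must remain.  SW traces are
    converted from dimensionless to SI units using the scales recorded in
    the trace metadata.  GRF peaks are extracted from each leg's stance
    profile (SLIP only): the first and last local maxima are reported as
    the weight-acceptance and push-off peaks; a unimodal profile yields
    equal peaks and sets ``degenerate_grf_shape``.
    """
    tscale = trace.meta.get("time_scale", 1.0)
    lscale = trace.meta.get("length_scale", 1.0)

    if trace.model is Model.SW:
        contact_kind = EventKind.HEELSTRIKE
    else:
        contact_kind = EventKind.TOUCHDOWN
    contacts = [e for e in trace.events if e.kind is contact_kind]

    first = 2 * discard_strides
    needed = first + 2 * min_strides + 1
    if len(contacts) < needed:
        raise InsufficientStridesError(
            f"need at least {needed} contacts "
            f"({discard_strides} discarded + {min_strides} analysed strides), "
            f"got {len(contacts)}"
        )
    window = contacts[first:]
    tc = np.array([e.time for e in window]) * tscale
    step_durations = np.diff(tc)
    mean_step = float(np.mean(step_durations))
    cadence = 1.0 / mean_step
    stride_duration = 2.0 * mean_step

    # forward COM travel between contacts
    xc = np.interp([e.time for e in window], trace.times, trace.com_x) * lscale
    total_travel = float(xc[-1] - xc[0])
    total_time = float(tc[-1] - tc[0])
    walking_speed = total_travel / total_time
    # stride length: same-leg contact-to-contact travel, averaged
    stride_lengths = xc[2:] - xc[:-2]
    stride_length = float(np.mean(stride_lengths))

    if trace.model is Model.SW:
        # instantaneous double support: per-leg stance equals one step
        return GaitParameters(
            stride_length=stride_length,
            cadence=cadence,
            walking_speed=walking_speed,
            dls_fraction=0.0,
            sls_fraction=0.5,
            stance_fraction=0.5,
            stance_duration=mean_step,
            vgrf_peak1=math.nan,
            vgrf_peak2=math.nan,
            n_strides_averaged=(len(window) - 1) // 2,
        )

    t_start, t_end = window[0].time, window[-1].time
    dls, sls, stances = _slip_phase_durations(trace, t_start, t_end)
    dls_fraction = float(np.mean(dls)) * tscale / stride_duration if dls else math.nan
    sls_fraction = float(np.mean(sls)) * tscale / stride_duration if sls else math.nan
    stance_fraction = (
        float(np.mean([b - a for a, b, _ in stances])) * tscale / stride_duration
        if stances
        else math.nan
    )

    peak1, peak2, degenerate = _grf_peaks(trace, stances)

    return GaitParameters(
        stride_length=stride_length,
        cadence=cadence,
        walking_speed=walking_speed,
        dls_fraction=dls_fraction,
        sls_fraction=sls_fraction,
        stance_fraction=stance_fraction,
        stance_duration=stance_fraction * stride_duration,
        vgrf_peak1=peak1,
        vgrf_peak2=peak2,
        n_strides_averaged=(len(window) - 1) // 2,
        degenerate_grf_shape=degenerate,
    )


def _slip_phase_durations(trace, t_start, t_end):
    """Per-stride DLS/SLS durations and per-leg stance intervals in [t_start, t_end]."""
    events = [e for e in trace.events]
    dls, sls = [], []
    for a, b in zip(events, events[1:]):
        if not (t_start <= a.time and b.time <= t_end):
            continue
        if a.kind is EventKind.TOUCHDOWN and b.kind is EventKind.TAKEOFF:
            dls.append(b.time - a.time)
        elif a.kind is EventKind.TAKEOFF and b.kind is EventKind.TOUCHDOWN:
            sls.append(b.time - a.time)
    # stance of a leg: its touchdown to its next takeoff
    stances = []
    for i, e in enumerate(events):
        if e.kind is not EventKind.TOUCHDOWN or e.time < t_start:
            continue
        for later in events[i + 1 :]:
            if later.kind is EventKind.TAKEOFF and later.leg == e.leg:
                if later.time <= t_end:
                    stances.append((e.time, later.time, e.leg))
                break
    return dls, sls, stances


def _grf_peaks(trace, stances):
    """First/last local maxima of each stance-phase GRF profile, averaged."""
    p1s, p2s = [], []
    degenerate = False
    for t0, t1, leg in stances:
        mask = (trace.times >= t0) & (trace.times <= t1)
        prof = (trace.grf_left if leg == "left" else trace.grf_right)[mask]
        if len(prof) < 3:
            continue
        idx, _ = find_peaks(prof)
        if len(idx) >= 2:
            p1s.append(prof[idx[0]])
            p2s.append(prof[idx[-1]])
        else:
            peak = float(np.max(prof))
            p1s.append(peak)
            p2s.append(peak)
            degenerate = True
    if not p1s:
        return math.nan, math.nan, True
    return float(np.mean(p1s)), float(np.mean(p2s)), degenerate


@dataclass
class TrendVector:
    """Per-BWS-level values of one gait parameter (raw and normalised)."""

    parameter: str
    levels: tuple[int, ...]       # percent, spaced by 5
    values: np.ndarray            # raw values; nan at infeasible levels
    feasible: np.ndarray          # bool per level
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if len(levels) > 1 and not np.all(np.diff(levels) == 5):
            raise ValueError("BWS levels must be spaced by 5 percentage points")
        self.values = np.asarray(self.values, dtype=float)
        self.feasible = np.asarray(self.feasible, dtype=bool)
        self.normalized = normalize_trend(self.values, self.feasible)


def normalize_trend(raw: np.ndarray, feasible: np.ndarray) -> np.ndarray:
    """Normalise a trend by its 0 %-BWS value; infeasible levels become 0.

    ``raw[0]`` is the value at 0 % BWS and must exist and be nonzero.
    """
    raw = np.asarray(raw, dtype=float)
    feasible = np.asarray(feasible, dtype=bool)
    if raw.shape != feasible.shape:
        raise ValueError("raw and feasible must have the same length")
    if not feasible[0] or not np.isfinite(raw[0]) or raw[0] == 0.0:
        raise ValueError("trend value at 0% BWS must exist and be nonzero")
    out = np.where(feasible, raw / raw[0], 0.0)
    out = np.where(np.isfinite(out), out, 0.0)
    return out


def mrmse(p_n: np.ndarray, p_h: np.ndarray, denominator: int | None = None) -> float:
    """RMS error (percent) of a normalised model trend vs the human reference.

    Both vectors cover the levels 5-40 % (8 entries); infeasible model
    levels must already be zeroed (the penalisation).  ``denominator``
    defaults to the number of levels.
    """
    p_n = np.asarray(p_n, dtype=float)
    p_h = np.asarray(p_h, dtype=float)
    if p_n.shape != p_h.shape or p_n.ndim != 1 or p_n.size == 0:
        raise ValueError("p_n and p_h must be equal-length non-empty vectors")
    if denominator is None:
        denominator = p_n.size
    return float(np.sqrt(np.sum((p_h - p_n) ** 2) / denominator) * 100.0)


def modela_w(v: float, f: float, l: float, g: float = 9.81) -> float:
    """Dimensionless gait-dynamics number ``(2gl/v^2 + (f l / v)^2)^-1``.

    Combines walking speed ``v`` (m/s), step frequency ``f`` (steps/s), leg
    length ``l`` (m) and gravity; together with the Froude number it
    characterises dynamic similarity of gaits.
    """
    if v <= 0:
        raise ValueError(f"walking speed v={v} must be > 0")
    if f <= 0 or l <= 0 or g <= 0:
        raise ValueError("f, l and g must be > 0")
    return 1.0 / (2.0 * g * l / v**2 + (f * l / v) ** 2)


def delta_gd(mw: np.ndarray, mw0: float, denominator: int | None = None) -> float:
    """Loss of dynamic similarity (percent): RMS change of modela-w.

    ``mw`` holds modela-w at the feasible levels between 5 % and 35 %
    (up to 7 entries; fewer when the walker fails earlier), ``mw0`` the
    value at 0 % BWS.
    """
    mw = np.asarray(mw, dtype=float)
    if mw.size == 0:
        raise ValueError("mw must be non-empty")
    if denominator is None:
        denominator = mw.size
    return float(np.sqrt(np.sum((mw - mw0) ** 2) / denominator) * 100.0)


@dataclass
class SimilarityMetrics:
    """Bundle of comparison statistics for one model x strategy."""

    modela_w_per_level: dict[int, float]
    delta_gd: float
    mrmse_per_parameter: dict[tuple[str, str], float]  # (parameter, environment)
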