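"""Simulation trace container and CSV export."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Model

#: fixed float formatting for deterministic byte-identical CSV output
FLOAT_FMT = "%.12g"


class Termination(str, enum.Enum):
    STEP_BUDGET_REACHED = "step_budget_reached"
    FELL = "fell"
    MOVED_BACKWARD = "moved_backward"
    TOOK_FLIGHT = "took_flight"
    INTEGRATION_FAILURE = "integration_failure"


class EventKind(str, enum.Enum):
    HEELSTRIKE = "heelstrike"
    TOUCHDOWN = "touchdown"
    TAKEOFF = "takeoff"


@dataclass
class Event:
    time: float
    kind: EventKind
    leg: str  # "left" | "right"


@dataclass
class SimulationTrace:
    """Time series of a hybrid gait simulation.

    ``times`` is strictly increasing except at hybrid transitions, where the
    pre- and post-transition samples share a time stamp.  SW traces are in
    dimensionless units (times in units of sqrt(l/g), lengths in units of
    l); SLIP traces are in SI units.  ``com_x`` is the cumulative forward
    position of the COM, used for stride-length extraction.
    """

    model: Model
    times: np.ndarray
    states: np.ndarray          # (n, state_dim)
    com_x: np.ndarray           # (n,)
    com_y: np.ndarray           # (n,)
    grf_left: np.ndarray        # (n,), N; zeros for SW
    grf_right: np.ndarray       # (n,), N; zeros for SW
    phase: list[str]
    events: list[Event]
    termination: Termination
    steps_completed: int
    state_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("states", "com_x", "com_y", "grf_left", "grf_right"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} not aligned to times ({n} samples)")
        if len(self.phase) != n:
            raise ValueError("phase not aligned to times")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def event_times(self, kind: EventKind | None = None) -> np.ndarray:
        return np.array(
            [e.time for e in self.events if kind is None or e.kind is kind]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "time", self.times)
        df["com_x"] = self.com_x
        df["com_y"] = self.com_y
        df["grf_left"] = self.grf_left
        df["grf_right"] = self.grf_right
        df["phase"] = self.phase
        return df

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [e.time for e in self.events],
                "kind": [e.kind.value for e in self.events],
                "leg": [e.leg for e in self.events],
            }
        )


def write_trace(trace: SimulationTrace, path: str | Path) -> None:
    """Write a trace to ``<path>`` and its event log to ``<path stem>_events.csv``.

    Output is byte-deterministic for identical traces (fixed column order
    and float formatting).
    """
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    events_path = path.with_name(path.stem + "_events" + path.suffix)
    trace.events_frame().to_csv(events_path, index=False, float_format=FLOAT_FMT)
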