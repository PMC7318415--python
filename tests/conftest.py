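"""Shared fixtures: session-scoped baseline simulations (they are pure)."""

from __future__ import annotations

import numpy as np
import pytest

from bwsim import (
    SLIPParams,
    SWParams,
    UnloadingConfig,
    simulate_slip,
    simulate_sw,
    slip_initial_state,
    sw_initial_state,
)

ORIGINAL_SLIP_SPEED = 1.1185
ORIGINAL_SW_STEP_LENGTH = 0.7167


@pytest.fixture(scope="session")
def slip_params() -> SLIPParams:
    return SLIPParams()


@pytest.fixture(scope="session")
def sw_params() -> SWParams:
    return SWParams()


@pytest.fixture(scope="session")
def slip_baseline_trace(slip_params):
    """Unsupported SLIP walk, 20 steps from the reference initial speed."""
    init = slip_initial_state(ORIGINAL_SLIP_SPEED, slip_params)
    return simulate_slip(
        slip_params, UnloadingConfig(strategy="cf", u=0.0), init, step_budget=20
    )


@pytest.fixture(scope="session")
def sw_baseline_trace(sw_params):
    """Unsupported Simplest Walker, 20 steps on its calibrated limit cycle."""
    init = sw_initial_state(ORIGINAL_SW_STEP_LENGTH)
    return simulate_sw(
        sw_params, UnloadingConfig(strategy="cf", u=0.0), init, step_budget=20
    )


def interp_states(trace, t_grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of every state component onto a common grid."""
    return np.column_stack(
        [np.interp(t_grid, trace.times, trace.states[:, j])
         for j in range(trace.states.shape[1])]
    )
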