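"""Gait-parameter extraction and the trend/similarity statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bwsim import (
    EventKind,
    InsufficientStridesError,
    Model,
    SimulationTrace,
    Termination,
    delta_gd,
    extract_gait_parameters,
    modela_w,
    mrmse,
    normalize_trend,
)
from bwsim.metrics import TrendVector
from bwsim.trace import Event


def synthetic_sw_trace(step_duration=0.55, step_length=0.6, n_steps=20,
                       time_scale=1.0):
    """Exactly periodic walking trace (SW layout, dimensionless units)."""
    times, events = [0.0], []
    com_x = [0.0]
    legs = ("left", "right")
    for i in range(1, n_steps + 1):
        t = i * step_duration
        times.append(t)
        com_x.append(i * step_length)
        events.append(Event(t, EventKind.HEELSTRIKE, legs[i % 2]))
    n = len(times)
    return SimulationTrace(
        model=Model.SW,
        times=np.array(times),
        states=np.zeros((n, 4)),
        com_x=np.array(com_x),
        com_y=np.ones(n),
        grf_left=np.zeros(n),
        grf_right=np.zeros(n),
        phase=["stance"] * n,
        events=events,
        termination=Termination.STEP_BUDGET_REACHED,
        steps_completed=n_steps,
        state_names=("theta", "phi", "theta_dot", "phi_dot"),
        meta={"time_scale": time_scale, "length_scale": 1.0},
    )


class TestExtractGaitParameters:
    def test_cadence_is_inverse_step_duration(self):
        gp = extract_gait_parameters(synthetic_sw_trace(step_duration=0.55))
        assert gp.cadence == pytest.approx(1 / 0.55, rel=1e-12)
        assert gp.cadence == pytest.approx(1.8182, abs=1e-4)

    def test_stride_is_twice_step_for_symmetric_gait(self):
        gp = extract_gait_parameters(synthetic_sw_trace(step_length=0.6))
        assert gp.stride_length == pytest.approx(1.2, rel=1e-12)
        assert gp.walking_speed == pytest.approx(0.6 / 0.55, rel=1e-12)

    def test_dimensionless_time_scaling(self):
        tscale = math.sqrt(1 / 9.81)
        gp = extract_gait_parameters(synthetic_sw_trace(time_scale=tscale))
        assert gp.cadence == pytest.approx(1 / (0.55 * tscale), rel=1e-12)

    def test_too_few_strides_rejected(self):
        with pytest.raises(InsufficientStridesError):
            extract_gait_parameters(synthetic_sw_trace(n_steps=12))

    def test_transient_discard_is_configurable(self):
        gp = extract_gait_parameters(synthetic_sw_trace(n_steps=11),
                                     discard_strides=0)
        assert gp.n_strides_averaged >= 5

    def test_slip_phase_fractions_sum_to_one(self, slip_baseline_trace):
        """Event-log bookkeeping: 2 SLS + 2 DLS fractions = 1 per stride."""
        gp = extract_gait_parameters(slip_baseline_trace)
        assert 2 * gp.sls_fraction + 2 * gp.dls_fraction == pytest.approx(1.0, abs=1e-3)
        assert gp.stance_fraction == pytest.approx(
            gp.sls_fraction + 2 * gp.dls_fraction, abs=1e-3
        )
        assert gp.n_strides_averaged >= 5

    def test_slip_grf_has_two_peaks_at_baseline(self, slip_baseline_trace):
        gp = extract_gait_parameters(slip_baseline_trace)
        assert not gp.degenerate_grf_shape
        assert gp.vgrf_peak1 > 0 and gp.vgrf_peak2 > 0

    def test_time_reversed_trace_same_cadence_and_stride(self):
        tr = synthetic_sw_trace()
        t_end, x_end = tr.times[-1], tr.com_x[-1]
        rev = SimulationTrace(
            model=tr.model,
            times=(t_end - tr.times)[::-1].copy(),
            states=tr.states[::-1].copy(),
            com_x=(x_end - tr.com_x)[::-1].copy(),
            com_y=tr.com_y[::-1].copy(),
            grf_left=tr.grf_left[::-1].copy(),
            grf_right=tr.grf_right[::-1].copy(),
            phase=list(reversed(tr.phase)),
            events=[Event(t_end - e.time, e.kind, e.leg) for e in reversed(tr.events)],
            termination=tr.termination,
            steps_completed=tr.steps_completed,
            state_names=tr.state_names,
            meta=dict(tr.meta),
        )
        a = extract_gait_parameters(tr)
        b = extract_gait_parameters(rev)
        assert a.cadence == pytest.approx(b.cadence, rel=1e-12)
        assert a.stride_length == pytest.approx(b.stride_length, rel=1e-12)


class TestNormalizeTrend:
    def test_constant_raw_gives_ones(self):
        out = normalize_trend(np.full(5, 3.3), np.ones(5, bool))
        np.testing.assert_array_equal(out, np.ones(5))

    def test_infeasible_levels_penalised_to_zero(self):
        out = normalize_trend(np.array([2.0, np.nan, np.nan]),
                              np.array([True, False, False]))
        np.testing.assert_array_equal(out, [1.0, 0.0, 0.0])

    def test_simple_ratio(self):
        out = normalize_trend(np.array([2.0, 1.0]), np.array([True, True]))
        np.testing.assert_array_equal(out, [1.0, 0.5])

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_trend(np.array([0.0, 1.0]), np.array([True, True]))

    def test_trend_vector_requires_five_percent_spacing(self):
        with pytest.raises(ValueError):
            TrendVector("cadence", (0, 10), np.array([1.0, 0.9]),
                        np.array([True, True]))


class TestMrmse:
    def test_identity_is_zero(self):
        p = np.linspace(1.0, 0.8, 8)
        assert mrmse(p, p) == 0.0

    def test_single_penalised_level(self):
        """One zeroed level against a unit reference: sqrt(1/8)*100."""
        p_n = np.ones(8)
        p_n[3] = 0.0
        assert mrmse(p_n, np.ones(8)) == pytest.approx(35.355339, abs=1e-5)

    def test_uniform_offset(self):
        assert mrmse(np.ones(8) - 0.1, np.ones(8)) == pytest.approx(10.0, rel=1e-12)

    def test_printed_denominator_override(self):
        p_n = np.ones(8)
        p_n[3] = 0.0
        assert mrmse(p_n, np.ones(8), denominator=3) == pytest.approx(
            math.sqrt(1 / 3) * 100, rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mrmse(np.ones(8), np.ones(7))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        p_n, p_h = rng.uniform(0, 1, 8), rng.uniform(0.5, 1, 8)
        perm = rng.permutation(8)
        assert mrmse(p_n, p_h) == pytest.approx(mrmse(p_n[perm], p_h[perm]), rel=1e-12)

    def test_strictly_increasing_in_any_single_deviation(self):
        p_h = np.ones(8)
        p_n = np.ones(8)
        p_n[2] = 0.9
        base = mrmse(p_n, p_h)
        p_n[2] = 0.8
        assert mrmse(p_n, p_h) > base


class TestModelaW:
    def test_reference_value(self):
        # 1 / (2*9.81/1.2^2 + (1.8/1.2)^2) = 1/(13.625 + 2.25)
        assert modela_w(v=1.2, f=1.8, l=1.0, g=9.81) == pytest.approx(0.06300, abs=1e-5)

    @settings(max_examples=60, deadline=None)
    @given(
        v=st.floats(0.3, 3.0),
        f=st.floats(0.5, 4.0),
        l=st.floats(0.5, 1.5),
        g=st.floats(5.0, 15.0),
    )
    def test_matches_direct_formula(self, v, f, l, g):
        expected = (2.0 * g * l / v**2 + (f * l / v) ** 2) ** -1
        assert modela_w(v, f, l, g) == pytest.approx(expected, rel=1e-14)

    def test_monotone_increasing_in_speed(self):
        vals = [modela_w(v, 1.8, 1.0) for v in np.linspace(0.5, 2.5, 9)]
        assert np.all(np.diff(vals) > 0)

    def test_doubling_gravity_decreases_value(self):
        assert modela_w(1.2, 1.8, 1.0, 19.62) < modela_w(1.2, 1.8, 1.0, 9.81)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            modela_w(0.0, 1.8, 1.0)


class TestDeltaGd:
    def test_constant_series_is_zero(self):
        assert delta_gd(np.full(7, 0.063), 0.063) == 0.0

    def test_uniform_shift(self):
        assert delta_gd(np.full(7, 0.063 + 0.02), 0.063) == pytest.approx(2.0, rel=1e-12)

    def test_single_level(self):
        assert delta_gd(np.array([0.113]), 0.063) == pytest.approx(5.0, rel=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            delta_gd(np.array([]), 0.063)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        mw = rng.uniform(0.02, 0.1, 7)
        assert delta_gd(mw, 0.063) == pytest.approx(
            delta_gd(mw[rng.permutation(7)], 0.063), rel=1e-12
        )
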