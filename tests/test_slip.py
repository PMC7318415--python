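"""Bipedal walking SLIP: dynamics, hybrid events, conservation and symmetry."""

import math

import numpy as np
import pytest

from bwsim import (
    EventKind,
    SLIPParams,
    Termination,
    UnloadingConfig,
    simulate_slip,
    slip_derivatives,
    slip_initial_state,
    tune_spring,
)
from bwsim.slip import leg_force_coeff, touchdown_height, ts_force


def make_ts(u, m=80.0, c=2.336, y_c0=0.944, g=9.81):
    k_s, dl0, omega = tune_spring(u, m, c, g)
    return UnloadingConfig(
        strategy="ts", u=u, k_s=k_s, delta_l0=dl0, omega=omega, y_c0=y_c0
    )


class TestDerivatives:
    def test_vertical_uncompressed_leg_cf(self, slip_params):
        """Stance leg exactly vertical at rest length: pure reduced gravity."""
        u = 0.3
        s = np.array([0.0, slip_params.l0, 1.0, 0.0])
        d = slip_derivatives(s, slip_params, UnloadingConfig(strategy="cf", u=u), (0.0,))
        assert d[3] == pytest.approx(-(1 - u) * slip_params.g, rel=1e-14)
        assert d[2] == 0.0

    def test_vertical_uncompressed_leg_cw(self, slip_params):
        u = 0.3
        s = np.array([0.0, slip_params.l0, 1.0, 0.0])
        d = slip_derivatives(s, slip_params, UnloadingConfig(strategy="cw", u=u), (0.0,))
        assert d[3] == pytest.approx(-slip_params.g * (1 - u) / (1 + u), rel=1e-14)

    def test_strategies_coincide_unsupported(self, slip_params):
        rng = np.random.default_rng(3)
        cfgs = [
            UnloadingConfig(strategy="cf", u=0.0),
            UnloadingConfig(strategy="cw", u=0.0),
            UnloadingConfig(strategy="ts", u=0.0),
        ]
        for _ in range(25):
            s = rng.uniform([-0.3, 0.7, 0.2, -0.8], [0.3, 1.1, 1.8, 0.8])
            feet = (rng.uniform(-0.5, 0.5),)
            outs = [slip_derivatives(s, slip_params, c, feet) for c in cfgs]
            np.testing.assert_array_equal(outs[0], outs[1])
            np.testing.assert_array_equal(outs[0], outs[2])

    def test_leg_spring_is_unilateral(self, slip_params):
        # beyond rest length the leg exerts no force
        assert leg_force_coeff(0.0, 1.2 * slip_params.l0, 0.0, slip_params) == 0.0
        assert leg_force_coeff(0.0, 0.9 * slip_params.l0, 0.0, slip_params) > 0.0

    def test_zero_leg_length_singularity(self, slip_params):
        with pytest.raises(ZeroDivisionError):
            leg_force_coeff(0.0, 0.0, 0.0, slip_params)

    def test_tuned_spring_inertial_compensation_identity(self, slip_params):
        """For harmonic attachment motion at the tuning frequency,
        F_ts = u m (g + y_c'') exactly (the design identity)."""
        u, m, g = 0.35, slip_params.m, slip_params.g
        cfg = make_ts(u, m=m, c=1.9, y_c0=0.95, g=g)
        omega, A = cfg.omega, 0.04
        t = np.linspace(0.0, 2.0, 501)
        y = cfg.y_c0 + A * np.sin(omega * t)
        y_ddot = -A * omega**2 * np.sin(omega * t)
        f = np.array([ts_force(yi, slip_params, cfg) for yi in y])
        np.testing.assert_allclose(f, u * m * (g + y_ddot), rtol=1e-12, atol=1e-9)


@pytest.fixture(scope="module")
def slip_converged_trace(slip_params):
    """Long run: the transient from the standing start has died out."""
    init = slip_initial_state(1.1185, slip_params)
    return simulate_slip(slip_params, UnloadingConfig(strategy="cf", u=0.0),
                         init, step_budget=50)


class TestSimulateSLIP:
    def test_reference_gait_walks_twenty_steps(self, slip_baseline_trace):
        assert slip_baseline_trace.steps_completed == 20
        assert slip_baseline_trace.termination is Termination.STEP_BUDGET_REACHED

    def test_phase_sequence_alternates(self, slip_baseline_trace):
        kinds = [e.kind for e in slip_baseline_trace.events]
        # touchdown and takeoff strictly alternate, starting with touchdown
        assert kinds[0] is EventKind.TOUCHDOWN
        assert all(a is not b for a, b in zip(kinds, kinds[1:]))

    def test_touchdown_occurs_at_landing_height(self, slip_baseline_trace, slip_params):
        y_td = touchdown_height(slip_params)
        for e in slip_baseline_trace.events:
            if e.kind is EventKind.TOUCHDOWN:
                y_at = np.interp(e.time, slip_baseline_trace.times, slip_baseline_trace.com_y)
                assert y_at == pytest.approx(y_td, abs=1e-6)

    def test_grf_nonnegative_and_zero_off_contact(self, slip_baseline_trace):
        tr = slip_baseline_trace
        assert np.all(tr.grf_left >= 0.0)
        assert np.all(tr.grf_right >= 0.0)
        sls = np.array(tr.phase) == "SLS"
        # in single stance exactly one leg can carry force
        both = (tr.grf_left > 0) & (tr.grf_right > 0)
        assert not np.any(both & sls)

    def test_force_balance_each_sample(self, slip_baseline_trace, slip_params):
        """grf_left + grf_right + F_u - m g = m y'' at every recorded sample."""
        tr = slip_baseline_trace
        m, g = slip_params.m, slip_params.g
        cfg = UnloadingConfig(strategy="cf", u=0.0)
        for i in range(0, tr.n_samples, 7):
            feet = [
                fp
                for fp in (tr.meta["fp_trailing"][i], tr.meta["fp_leading"][i])
                if not math.isnan(fp)
            ]
            ay = slip_derivatives(tr.states[i], slip_params, cfg, tuple(feet))[3]
            total_grf = tr.grf_left[i] + tr.grf_right[i]
            assert m * ay == pytest.approx(total_grf - m * g, rel=1e-9, abs=1e-6)

    def test_steady_gait_is_symmetric(self, slip_converged_trace):
        """On the limit cycle consecutive steps have equal duration and length."""
        tr = slip_converged_trace
        evs = tr.event_times(EventKind.TOUCHDOWN)
        durs = np.diff(evs)[-6:]
        assert np.ptp(durs) < 1e-5 * np.mean(durs)
        xs = np.interp(evs, tr.times, tr.com_x)
        lens = np.diff(xs)[-6:]
        assert np.ptp(lens) < 1e-5 * np.mean(lens)

    def test_left_right_grf_profiles_mirror(self, slip_converged_trace):
        tr = slip_converged_trace
        tds = [e for e in tr.events if e.kind is EventKind.TOUCHDOWN]
        # compare two consecutive steady stance profiles on a normalized grid
        a, b = tds[-4], tds[-3]
        dur = b.time - a.time
        grid = np.linspace(0, dur, 200)
        pa = np.interp(a.time + grid, tr.times,
                       tr.grf_left if a.leg == "left" else tr.grf_right)
        pb = np.interp(b.time + grid, tr.times,
                       tr.grf_left if b.leg == "left" else tr.grf_right)
        np.testing.assert_allclose(pa, pb, atol=5e-3 * max(pa.max(), 1.0))

    def test_zero_step_budget_rejected(self, slip_params):
        with pytest.raises(ValueError):
            simulate_slip(slip_params, UnloadingConfig(strategy="cf", u=0.0),
                          slip_initial_state(), step_budget=0)

    def test_extreme_unloading_takes_flight(self, slip_params):
        """Raising u until the springs unload entirely ends in flight."""
        init = slip_initial_state(1.2, slip_params)
        tr = simulate_slip(slip_params, UnloadingConfig(strategy="cf", u=0.6),
                           init, step_budget=20)
        assert tr.termination is Termination.TOOK_FLIGHT


def mechanical_energy(tr, slip_params, u):
    """0.5 m v^2 + m (1-u) g y + sum of leg-spring energies (compression only)."""
    m, g, k, l0 = slip_params.m, slip_params.g, slip_params.k, slip_params.l0
    E = np.empty(tr.n_samples)
    for i in range(tr.n_samples):
        x, y, vx, vy = tr.states[i]
        e = 0.5 * m * (vx**2 + vy**2) + m * (1 - u) * g * y
        for fp in (tr.meta["fp_trailing"][i], tr.meta["fp_leading"][i]):
            if not math.isnan(fp):
                compression = max(l0 - math.hypot(x - fp, y), 0.0)
                e += 0.5 * k * compression**2
        E[i] = e
    return E


class TestConservation:
    @pytest.mark.parametrize("u", [0.0, 0.3])
    def test_cf_energy_conserved_over_a_stride(self, slip_params, u):
        """Constant-force unloading is a conservative reduction of gravity."""
        init = slip_initial_state(1.1185, slip_params)
        tr = simulate_slip(slip_params, UnloadingConfig(strategy="cf", u=u),
                           init, step_budget=12)
        assert tr.steps_completed == 12
        tds = tr.event_times(EventKind.TOUCHDOWN)
        stride = (tr.times >= tds[-3]) & (tr.times <= tds[-1])
        E = mechanical_energy(tr, slip_params, u)[stride]
        assert np.ptp(E) / abs(E.mean()) < 1e-6

    def test_cw_equals_cf_with_effective_gravity(self, slip_params):
        """CW vertical dynamics are CF dynamics under g (1-u)/(1+u)."""
        u = 0.3
        init = slip_initial_state(1.1185, slip_params)
        tr_cw = simulate_slip(slip_params, UnloadingConfig(strategy="cw", u=u),
                              init, step_budget=10)
        g_eff = slip_params.g * (1 - u) / (1 + u)
        params_eff = SLIPParams(m=slip_params.m, l0=slip_params.l0,
                                k=slip_params.k, alpha=slip_params.alpha, g=g_eff)
        tr_cf = simulate_slip(params_eff, UnloadingConfig(strategy="cf", u=0.0),
                              init, step_budget=10)
        assert tr_cw.steps_completed == tr_cf.steps_completed
        t_end = min(tr_cw.times[-1], tr_cf.times[-1])
        grid = np.linspace(0.0, t_end, 400)
        for j in range(4):
            a = np.interp(grid, tr_cw.times, tr_cw.states[:, j])
            b = np.interp(grid, tr_cf.times, tr_cf.states[:, j])
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-7)
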