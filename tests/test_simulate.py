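"""Integrators: Euler-Maruyama, exact SSA, population averaging."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from oscent.models import (
    KF_TIME_SCALE,
    AmplitudePhaseParams,
    ForcingProgram,
    KimForgerParams,
    ParameterError,
    VDP_NOISE_INDUCED,
    kim_forger_drift,
)
from oscent.metrics import detect_peaks, free_running_period
from oscent.simulate import (
    SimConfig,
    euler_maruyama,
    gillespie_ssa,
    limit_cycle_point,
    select_method,
    simulate_population,
)

QUIET = ForcingProgram(T=1.0, Imax=0.0)


class TestEulerMaruyama:
    def test_single_step_hand_computed(self):
        # one deterministic step from the fully repressed state
        cfg = SimConfig(dt=0.001, t_end=0.001)
        traj = euler_maruyama(KimForgerParams(), QUIET, cfg,
                              initial_state=np.array([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(
            traj.states[1], [1.0 - KF_TIME_SCALE * 0.001, 1.0, 1.0],
            rtol=1e-14)

    def test_unit_free_running_period(self, kf_free_run):
        per = free_running_period(kf_free_run, transient=20.0,
                                  min_separation=0.5)
        assert per == pytest.approx(1.0, abs=0.01)

    def test_deterministic_path_is_seed_independent(self, kf_params):
        t1 = euler_maruyama(kf_params, QUIET, SimConfig(t_end=5.0, seed=1))
        t2 = euler_maruyama(kf_params, QUIET, SimConfig(t_end=5.0, seed=999))
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_stochastic_path_reproducible(self):
        p = KimForgerParams(sigma=0.01)
        t1 = euler_maruyama(p, QUIET, SimConfig(t_end=5.0, seed=7))
        t2 = euler_maruyama(p, QUIET, SimConfig(t_end=5.0, seed=7))
        t3 = euler_maruyama(p, QUIET, SimConfig(t_end=5.0, seed=8))
        np.testing.assert_array_equal(t1.states, t2.states)
        assert not np.array_equal(t1.states, t3.states)

    def test_state_floor_aborts(self):
        p = KimForgerParams(sigma=0.2)
        cfg = SimConfig(t_end=20.0, seed=3, state_floor=-0.05, method="cle")
        from oscent.simulate import SimulationError

        with pytest.raises(SimulationError):
            euler_maruyama(p, QUIET, cfg)

    def test_amplitude_phase_radius_relaxation(self):
        # sigma = 0: dR/dt = lam * R * (A - R), logistic convergence to A
        p = AmplitudePhaseParams()
        cfg = SimConfig(t_end=10.0)
        traj = euler_maruyama(p, QUIET, cfg, initial_state=np.array([2.0, 0.0]))
        R = np.hypot(traj.states[:, 0], traj.states[:, 1])
        t = traj.times
        R0 = 2.0
        expected = p.amp / (1 + (p.amp / R0 - 1) * np.exp(-p.lam * p.amp * t))
        assert np.max(np.abs(R - expected)) < 5e-3
        assert R[-1] == pytest.approx(p.amp, abs=1e-3)

    def test_vdp_noise_induced_decays(self):
        cfg = SimConfig(t_end=80.0)
        traj = euler_maruyama(VDP_NOISE_INDUCED, QUIET, cfg,
                              initial_state=np.array([1.0, 0.0]))
        peaks = detect_peaks(traj, min_separation=3.0, min_prominence=0.001)
        assert len(peaks) >= 4
        assert np.all(np.diff(peaks.heights) < 0)

    def test_agrees_with_adaptive_solver(self, kf_params):
        # deterministic cross-check against an adaptive-step integrator
        state0 = limit_cycle_point(kf_params)
        horizon = 20.0
        cfg = SimConfig(dt=1e-5, t_end=horizon)
        em = euler_maruyama(kf_params, QUIET, cfg, initial_state=state0)
        sol = solve_ivp(
            lambda t, s: kim_forger_drift(s, kf_params, 0.0),
            (0.0, horizon), state0, method="LSODA",
            rtol=1e-10, atol=1e-12, dense_output=True)
        sub = slice(None, None, 1000)
        err = np.max(np.abs(em.states[sub] - sol.sol(em.times[sub]).T))
        assert err < 1e-3


class TestGillespie:
    def test_counts_are_non_negative_integers(self):
        p = KimForgerParams(omega_size=200)
        traj = gillespie_ssa(p, ForcingProgram(T=1.0, Imax=0.05),
                             SimConfig(t_end=5.0, seed=4))
        counts = traj.states * 200
        assert np.all(counts >= 0)
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_requires_system_size(self):
        with pytest.raises(ParameterError):
            gillespie_ssa(KimForgerParams(sigma=0.01), QUIET, SimConfig(t_end=1.0))

    def test_rejects_fractional_counts(self):
        p = KimForgerParams(omega_size=100)
        with pytest.raises(ParameterError):
            gillespie_ssa(p, QUIET, SimConfig(t_end=1.0),
                          initial_counts=[1.5, 0, 0])

    def test_oscillates_with_unit_period_at_large_omega(self):
        p = KimForgerParams(omega_size=40_000)
        traj = gillespie_ssa(p, QUIET, SimConfig(t_end=30.0, seed=11))
        per = free_running_period(traj, transient=10.0, min_separation=0.5)
        assert per == pytest.approx(1.0, abs=0.05)


class TestSelectMethod:
    @pytest.mark.parametrize("kwargs,expected", [
        ({"omega": 40_000}, "cle"),
        ({"omega": 500}, "ssa"),
        ({"sigma": 0.0}, "ode"),
        ({"sigma": 0.005}, "cle"),
        ({"sigma": 0.05}, "ssa"),
    ])
    def test_selection(self, kwargs, expected):
        assert select_method(**kwargs) == expected

    def test_requires_exactly_one_argument(self):
        with pytest.raises(ParameterError):
            select_method()
        with pytest.raises(ParameterError):
            select_method(omega=100, sigma=0.1)


class TestPopulation:
    def test_single_member_equals_mean(self):
        p = KimForgerParams(sigma=0.005)
        forcing = ForcingProgram(T=1.0, Imax=0.05)
        cfg = SimConfig(t_end=5.0, seed=2, n=1, record_members=True)
        pop = simulate_population(p, forcing, cfg)
        np.testing.assert_allclose(pop.member_outputs[0],
                                   pop.mean_trajectory.output(), rtol=1e-12)

    def test_deterministic_members_identical(self):
        p = KimForgerParams(sigma=0.0)
        cfg = SimConfig(t_end=3.0, seed=2, n=4, record_members=True)
        pop = simulate_population(p, QUIET, cfg)
        assert np.ptp(pop.member_outputs, axis=0).max() == 0.0

    def test_same_seed_bitwise_identical(self):
        p = KimForgerParams(sigma=0.01)
        forcing = ForcingProgram(T=1.0, Imax=0.05)
        cfg = SimConfig(t_end=5.0, seed=42, n=8)
        a = simulate_population(p, forcing, cfg)
        b = simulate_population(p, forcing, cfg)
        np.testing.assert_array_equal(a.mean_trajectory.states,
                                      b.mean_trajectory.states)

    def test_small_population_members_shared_by_larger(self):
        p = KimForgerParams(sigma=0.01)
        cfg_small = SimConfig(t_end=2.0, seed=5, n=2, record_members=True)
        cfg_big = SimConfig(t_end=2.0, seed=5, n=6, record_members=True)
        small = simulate_population(p, QUIET, cfg_small)
        big = simulate_population(p, QUIET, cfg_big)
        np.testing.assert_array_equal(small.member_outputs,
                                      big.member_outputs[:2])

    def test_mean_is_arithmetic_mean_of_members(self):
        p = KimForgerParams(sigma=0.01)
        cfg = SimConfig(t_end=2.0, seed=5, n=7, record_members=True)
        pop = simulate_population(p, QUIET, cfg)
        np.testing.assert_allclose(pop.member_outputs.mean(axis=0),
                                   pop.mean_trajectory.output(), rtol=1e-12)

    def test_variance_of_mean_scales_inversely_with_n(self):
        # var of the population mean across independent populations ~ 1/n
        p = KimForgerParams(sigma=0.01)
        n_values = [4, 16, 64]
        n_reps = 12
        probe = -1  # final time point
        variances = []
        for n in n_values:
            vals = []
            for rep in range(n_reps):
                cfg = SimConfig(t_end=3.0, seed=1000 + rep, n=n)
                pop = simulate_population(p, QUIET, cfg)
                vals.append(pop.mean_trajectory.output()[probe])
            variances.append(np.var(vals, ddof=1))
        slope = np.polyfit(np.log(n_values), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.35)

    def test_ssa_population_mean(self):
        p = KimForgerParams(omega_size=300)
        cfg = SimConfig(t_end=3.0, seed=9, n=5, record_members=True, method="ssa")
        pop = simulate_population(p, QUIET, cfg)
        np.testing.assert_allclose(pop.member_outputs.mean(axis=0),
                                   pop.mean_trajectory.output(), rtol=1e-12)
        assert pop.mean_trajectory.meta["method"] == "ssa"

    def test_auto_method_resolution(self):
        cfg = SimConfig(t_end=1.0, seed=0, n=2)
        pop = simulate_population(KimForgerParams(sigma=0.05), QUIET, cfg)
        assert pop.mean_trajectory.meta["method"] == "ssa"
        pop = simulate_population(KimForgerParams(sigma=0.005), QUIET, cfg)
        assert pop.mean_trajectory.meta["method"] == "cle"
        pop = simulate_population(KimForgerParams(), QUIET, cfg)
        assert pop.mean_trajectory.meta["method"] == "ode"

    def test_heterogeneous_thresholds_change_members(self):
        p = KimForgerParams()
        cfg = SimConfig(t_end=5.0, seed=3, n=2, record_members=True)
        pop = simulate_population(p, QUIET, cfg,
                                  member_A=np.array([0.08, 0.12]))
        assert not np.array_equal(pop.member_outputs[0], pop.member_outputs[1])

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            SimConfig(dt=0.0)
        with pytest.raises(ParameterError):
            SimConfig(n=0)
        with pytest.raises(ParameterError):
            SimConfig(method="magic")
        with pytest.raises(ParameterError):
            SimConfig(t_end=1.0, transient=2.0)
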