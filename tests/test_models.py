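"""Model definitions: repression kinetics, drifts, noise terms, forcing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscent.models import (
    KF_TIME_SCALE,
    AmplitudePhaseParams,
    ForcingProgram,
    KimForgerParams,
    ParameterError,
    PhaseShift,
    Pulse,
    VanDerPolParams,
    VDP_LIMIT_CYCLE,
    VDP_NOISE_INDUCED,
    amplitude_phase_drift,
    forcing_breakpoints,
    kim_forger_diffusion,
    kim_forger_drift,
    kim_forger_propensities,
    kim_forger_scheme,
    repression,
    sigma_from_system_size,
    square_input,
    system_size_from_sigma,
    vdp_drift,
    vdp_preset,
)

TAU = KF_TIME_SCALE


class TestRepression:
    @pytest.mark.parametrize("Z,A,expected", [
        (0.0, 0.1, 1.0),       # no repressor: maximal transcription
        (0.05, 0.1, 0.5),      # midpoint of the linear branch
        (0.2, 0.1, 0.0),       # saturated repression beyond the threshold
        (0.1, 0.1, 0.0),       # continuous at Z = A
    ])
    def test_closed_form(self, Z, A, expected):
        assert repression(Z, A) == pytest.approx(expected, abs=1e-15)

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            repression(0.5, 0.0)
        with pytest.raises(ParameterError):
            repression(0.5, -1.0)

    @given(st.floats(0.0, 10.0), st.floats(0.01, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, Z, A):
        v = repression(Z, A)
        assert 0.0 <= v <= 1.0
        assert repression(Z + 0.1, A) <= v + 1e-12


class TestKimForgerDrift:
    def test_fully_repressed_state(self):
        # f(1, 0.1) = 0, so only X decays
        np.testing.assert_allclose(
            kim_forger_drift((1, 1, 1), KimForgerParams()),
            TAU * np.array([-1.0, 0.0, 0.0]))

    def test_origin(self):
        np.testing.assert_allclose(
            kim_forger_drift((0, 0, 0), KimForgerParams()),
            TAU * np.array([1.0, 0.0, 0.0]))

    def test_fixed_point(self):
        # X = Y = Z = c with f(c, A) = c gives zero drift: c = A/(A+1)
        A = 0.1
        c = A / (A + 1.0)
        np.testing.assert_allclose(
            kim_forger_drift((c, c, c), KimForgerParams(A=A)),
            np.zeros(3), atol=1e-14)


class TestKimForgerDiffusion:
    def test_zero_noise_is_zero_matrix(self):
        G = kim_forger_diffusion((0.5, 0.5, 0.5), KimForgerParams(sigma=0.0), I=0.1)
        assert np.all(G == 0.0)

    def test_sparsity_pattern(self):
        s = 0.1
        G = kim_forger_diffusion((1.0, 0.0, 0.0), KimForgerParams(sigma=s))
        st_ = s * np.sqrt(TAU)
        expected = np.zeros((3, 7))
        expected[0, 0] = st_          # synthesis at rate f(0, A) = 1
        expected[0, 1] = -st_         # X decay, sqrt(1)
        expected[1, 3] = st_          # Y synthesis driven by X
        np.testing.assert_allclose(G, expected)

    def test_variance_matches_propensities(self):
        # per-row sum of squared noise coefficients == sigma^2 * (sum of the
        # corresponding propensities / Omega), on random states
        rng = np.random.default_rng(42)
        p = KimForgerParams(sigma=0.02)
        omega = 1.0e4
        for _ in range(100):
            X, Y, Z = rng.uniform(0.0, 0.5, size=3)
            I = rng.uniform(0.0, 0.1)
            G = kim_forger_diffusion((X, Y, Z), p, I)
            a = kim_forger_propensities(omega * X, omega * Y, omega * Z,
                                        omega, p.A, I) / omega
            row_var = (G ** 2).sum(axis=1)
            expected = p.sigma ** 2 * np.array([a[0] + a[1] + a[2],
                                                a[3] + a[4], a[5] + a[6]])
            np.testing.assert_allclose(row_var, expected, rtol=1e-10)


class TestSystemSizeScaling:
    @pytest.mark.parametrize("omega,sigma", [
        (40_000.0, 0.005),
        (1.0, 1.0),
        (1000.0, 1000.0 ** -0.5),
    ])
    def test_closed_form(self, omega, sigma):
        assert sigma_from_system_size(omega) == pytest.approx(sigma, rel=1e-12)
        assert system_size_from_sigma(sigma) == pytest.approx(omega, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ParameterError):
            sigma_from_system_size(0.0)
        with pytest.raises(ParameterError):
            sigma_from_system_size(-5.0)

    def test_params_derive_sigma_from_omega(self):
        p = KimForgerParams(omega_size=40_000)
        assert p.sigma == pytest.approx(0.005)

    def test_inconsistent_sigma_omega_rejected(self):
        with pytest.raises(ParameterError):
            KimForgerParams(sigma=0.01, omega_size=40_000)


class TestPropensities:
    def test_matches_drift_times_omega(self):
        # concentration <-> count consistency of the discrete scheme
        rng = np.random.default_rng(7)
        omega, A, I = 500.0, 0.1, 0.03
        scheme = kim_forger_scheme()
        for _ in range(50):
            x, y, z = rng.integers(0, 200, size=3)
            a = scheme.propensities(x, y, z, omega, A, I)
            assert np.all(a >= 0)
            X, Y, Z = x / omega, y / omega, z / omega
            expected = TAU * omega * np.array(
                [repression(Z, A), X, I, X, Y, Y, Z])
            np.testing.assert_allclose(a, expected, rtol=1e-12)

    def test_synthesis_shuts_off(self):
        a = kim_forger_propensities(0, 0, 60, omega=500, A=0.1, I=0.0)
        np.testing.assert_allclose(a, TAU * np.array([0, 0, 0, 0, 0, 0, 60.0]))

    def test_stoichiometry_shape(self):
        scheme = kim_forger_scheme()
        assert scheme.stoichiometry.shape == (7, 3)
        assert set(np.unique(scheme.stoichiometry)) <= {-1, 0, 1}


class TestPlanarModels:
    def test_vdp_fixed_point_and_sample(self):
        np.testing.assert_allclose(vdp_drift((0, 0), VDP_LIMIT_CYCLE), [0, 0])
        np.testing.assert_allclose(vdp_drift((1, 1), VDP_LIMIT_CYCLE), [1, -9])

    def test_vdp_presets(self):
        assert (VDP_LIMIT_CYCLE.d, VDP_LIMIT_CYCLE.B) == (2.0, 10.0)
        assert (VDP_NOISE_INDUCED.d, VDP_NOISE_INDUCED.B) == (-0.1, 1.0)
        assert vdp_preset("limit_cycle", sigma=0.2).sigma == 0.2
        with pytest.raises(ParameterError):
            vdp_preset("nope")

    def test_noise_induced_regime_is_damped(self):
        # linearization at the origin: eigenvalues of [[0, 1], [-1, d]]
        d = VDP_NOISE_INDUCED.d
        eig = np.linalg.eigvals(np.array([[0.0, 1.0], [-1.0, d]]))
        assert np.all(eig.real < 0)

    def test_amplitude_phase_on_cycle(self):
        p = AmplitudePhaseParams()
        np.testing.assert_allclose(amplitude_phase_drift((1, 0), p), [0, 1],
                                   atol=1e-15)
        np.testing.assert_allclose(amplitude_phase_drift((0, 0), p), [0, 0],
                                   atol=1e-15)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            AmplitudePhaseParams(lam=-1.0)
        with pytest.raises(ParameterError):
            VanDerPolParams(d=2, B=10, sigma=-0.1)


class TestSquareInput:
    def test_half_cycle_values(self):
        prog = ForcingProgram(T=1.0, Imax=0.05)
        assert square_input(0.25, prog) == 0.05
        assert square_input(0.5, prog) == 0.0   # boundary belongs to the off half
        assert square_input(0.999, prog) == 0.0
        assert square_input(1.0, prog) == 0.05

    def test_phase_shift_moves_the_window(self):
        prog = ForcingProgram(T=1.0, Imax=0.05,
                              events=(PhaseShift(time=0.0, shift=0.5),))
        assert square_input(0.25, prog) == 0.0
        assert square_input(0.75, prog) == 0.05

    def test_pulse_overrides(self):
        prog = ForcingProgram(T=1.0, Imax=0.05,
                              events=(Pulse(start=0.6, duration=0.2, amplitude=0.3),))
        assert square_input(0.55, prog) == 0.0
        assert square_input(0.7, prog) == 0.3
        assert square_input(0.81, prog) == 0.0

    @given(st.floats(0.2, 5.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_light_dose_per_cycle(self, T, Imax):
        # the square wave delivers Imax*T/2 per full cycle
        prog = ForcingProgram(T=T, Imax=Imax)
        t = np.linspace(0.0, T, 20001)
        dose = np.trapezoid(square_input(t, prog), t)
        assert dose == pytest.approx(Imax * T / 2, rel=2e-3, abs=1e-9)

    def test_event_validation(self):
        with pytest.raises(ParameterError):
            ForcingProgram(T=1.0, Imax=0.1,
                           events=(Pulse(0.5, 0.5, 0.1), Pulse(0.7, 0.5, 0.1)))
        with pytest.raises(ParameterError):
            ForcingProgram(T=1.0, Imax=0.1,
                           events=(PhaseShift(time=1.0, shift=1.5),))
        with pytest.raises(ParameterError):
            ForcingProgram(T=-1.0, Imax=0.1)

    def test_breakpoints_cover_switches(self):
        prog = ForcingProgram(T=1.0, Imax=0.05,
                              events=(PhaseShift(time=2.2, shift=0.3),))
        times, levels = forcing_breakpoints(prog, 4.0)
        assert times[0] == 0.0 and times[-1] == 4.0
        mids = (times[:-1] + times[1:]) / 2
        np.testing.assert_allclose(levels, square_input(mids, prog))
        # levels must match the signal everywhere within each interval
        probe = np.linspace(0.001, 3.999, 1717)
        idx = np.searchsorted(times, probe, side="right") - 1
        np.testing.assert_allclose(square_input(probe, prog), levels[idx])
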