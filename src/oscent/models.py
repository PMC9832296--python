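"""Oscillator model definitions and the periodic forcing signal.

Three limit-cycle oscillator models are provided as pure state-to-rate
mappings (no integrator logic):

* ``kim_forger`` -- a scaled three-variable negative-feedback loop
  (X -> Y -> Z --| X) representing a minimal cellular clock.  Molecular
  noise enters multiplicatively through the chemical Langevin equation,
  one noise channel per elementary reaction; the discrete counterpart is
  a seven-reaction birth/death scheme suitable for exact stochastic
  simulation.
* ``van_der_pol`` -- the canonical relaxation oscillator with additive
  input and additive Gaussian noise.  Two named presets: a limit-cycle
  regime (d=2, B=10) and a damped, noise-induced regime (d=-0.1, B=1).
* ``amplitude_phase`` -- a generic sinusoidal (lambda-omega) oscillator
  with relaxation rate ``lam``, amplitude ``amp`` and angular frequency
  ``omega``; additive noise.

Forcing is a square wave of period ``T`` and amplitude ``Imax`` (on for
the first half-cycle, off for the second), optionally decorated with
scheduled events: finite ``Pulse`` overrides and persistent ``PhaseShift``
advances of the input phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np

__all__ = [
    "SIGMA_OMEGA_EXPONENT",
    "KF_TIME_SCALE",
    "sigma_from_system_size",
    "system_size_from_sigma",
    "KimForgerParams",
    "VanDerPolParams",
    "AmplitudePhaseParams",
    "VDP_LIMIT_CYCLE",
    "VDP_NOISE_INDUCED",
    "vdp_preset",
    "Pulse",
    "PhaseShift",
    "ForcingProgram",
    "square_input",
    "forcing_breakpoints",
    "repression",
    "kim_forger_drift",
    "kim_forger_diffusion",
    "kim_forger_propensities",
    "kim_forger_scheme",
    "KF_STOICHIOMETRY",
    "ReactionScheme",
    "vdp_drift",
    "amplitude_phase_drift",
    "drift_function",
]


class ParameterError(ValueError):
    """Invalid model or forcing parameter."""


# Noise intensity vs system size: sigma = Omega ** SIGMA_OMEGA_EXPONENT.
# The exponent is a module constant so the alternative 1/Omega reading is
# a one-line change.
SIGMA_OMEGA_EXPONENT = -0.5

#: Time-scale factor of the Kim-Forger model.  Every reaction rate is
#: multiplied by this constant so that the deterministic oscillator has a
#: free-running period of exactly 1 (the unscaled negative-feedback loop
#: with A = 0.1 has natural period ~3.6597).  Noise channels scale as
#: sigma * sqrt(KF_TIME_SCALE * rate), i.e. the scaling acts on the
#: propensities, keeping sigma = Omega^(-1/2) intact.
KF_TIME_SCALE = 3.6597


def sigma_from_system_size(omega: float) -> float:
    """Noise intensity sigma implied by system size Omega (sigma = Omega^-1/2).

    Omega is the number-of-molecules scale of a single cell; larger cells
    fluctuate less.  Omega = 40 000 gives the working value sigma = 0.005.
    """
    if omega <= 0:
        raise ParameterError(f"system size Omega must be > 0, got {omega}")
    return float(omega) ** SIGMA_OMEGA_EXPONENT


def system_size_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_system_size` (Omega = sigma^-2)."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0 to imply a system size, got {sigma}")
    return float(sigma) ** (1.0 / SIGMA_OMEGA_EXPONENT)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KimForgerParams:
    """Parameters of the scaled Kim-Forger oscillator.

    A : repression threshold concentration (dimensionless).  The default
        0.1 yields high-amplitude limit-cycle oscillations with unit
        free-running period while keeping X clear of zero at moderate noise.
    sigma : noise intensity of the chemical Langevin equation (>= 0).
    omega_size : optional system size Omega; when given, sigma is derived
        as Omega^-1/2 (or checked for consistency if both are supplied).
    """

    A: float = 0.1
    sigma: Optional[float] = None
    omega_size: Optional[float] = None

    kind = "kim_forger"

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ParameterError(f"repression threshold A must be > 0, got {self.A}")
        if self.omega_size is not None:
            derived = sigma_from_system_size(self.omega_size)
            if self.sigma is None:
                object.__setattr__(self, "sigma", derived)
            elif not np.isclose(self.sigma, derived, rtol=1e-6, atol=1e-12):
                raise ParameterError(
                    f"sigma={self.sigma} inconsistent with omega_size={self.omega_size} "
                    f"(implies sigma={derived:.6g})"
                )
        elif self.sigma is None:
            object.__setattr__(self, "sigma", 0.0)
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def dim(self) -> int:
        return 3


@dataclass(frozen=True)
class VanDerPolParams:
    """Van der Pol oscillator: dX = Y, dY = -(B X^2 - d) Y - X + I, additive noise."""

    d: float
    B: float
    sigma: float = 0.0

    kind = "van_der_pol"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def dim(self) -> int:
        return 2


#: Relaxation limit-cycle regime.
VDP_LIMIT_CYCLE = VanDerPolParams(d=2.0, B=10.0)
#: Damped regime that oscillates sustainably only under noise.
VDP_NOISE_INDUCED = VanDerPolParams(d=-0.1, B=1.0)


def vdp_preset(name: str, sigma: float = 0.0) -> VanDerPolParams:
    """Return a named Van der Pol preset ('limit_cycle' or 'noise_induced')."""
    presets = {
        "limit_cycle": VDP_LIMIT_CYCLE,
        "noise_induced": VDP_NOISE_INDUCED,
    }
    try:
        base = presets[name]
    except KeyError:
        raise ParameterError(
            f"unknown Van der Pol preset {name!r}; choose from {sorted(presets)}"
        ) from None
    return VanDerPolParams(d=base.d, B=base.B, sigma=sigma)


@dataclass(frozen=True)
class AmplitudePhaseParams:
    """Sinusoidal (lambda-omega) oscillator with radial relaxation.

    lam : rate of return to the limit cycle (> 0)
    amp : limit-cycle amplitude (> 0)
    omega : angular frequency (> 0); free-running period is 2*pi/omega
    sigma : additive noise intensity (>= 0)
    """

    lam: float = 1.0
    amp: float = 1.0
    omega: float = 1.0
    sigma: float = 0.0

    kind = "amplitude_phase"

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.amp <= 0 or self.omega <= 0:
            raise ParameterError(
                f"lam, amp, omega must be > 0, got ({self.lam}, {self.amp}, {self.omega})"
            )
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def dim(self) -> int:
        return 2


ModelParams = Union[KimForgerParams, VanDerPolParams, AmplitudePhaseParams]


# ---------------------------------------------------------------------------
# Forcing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pulse:
    """Finite override of the input during [start, start + duration)."""

    start: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError(f"pulse duration must be > 0, got {self.duration}")
        if self.amplitude < 0:
            raise ParameterError(f"pulse amplitude must be >= 0, got {self.amplitude}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def time(self) -> float:
        return self.start


@dataclass(frozen=True)
class PhaseShift:
    """Persistent advance of the input phase by ``shift`` from ``time`` onward."""

    time: float
    shift: float


@dataclass(frozen=True)
class ForcingProgram:
    """Square-wave input of period T and amplitude Imax, plus scheduled events.

    The base signal is ``Imax`` for the first half of every period and 0
    for the second half (a day-night cycle).  ``PhaseShift`` events advance
    the input phase persistently (jet lag); ``Pulse`` events override the
    signal with their own amplitude for a finite window.
    """

    T: float
    Imax: float
    events: Tuple[Union[Pulse, PhaseShift], ...] = ()

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ParameterError(f"input period T must be > 0, got {self.T}")
        if self.Imax < 0:
            raise ParameterError(f"input amplitude Imax must be >= 0, got {self.Imax}")
        events = tuple(self.events)
        times = [e.time for e in events]
        if times != sorted(times):
            raise ParameterError("forcing events must be time-ordered")
        pulses = [e for e in events if isinstance(e, Pulse)]
        for a, b in zip(pulses, pulses[1:]):
            if b.start < a.end:
                raise ParameterError(
                    f"overlapping pulses at t={a.start} and t={b.start}"
                )
        for e in events:
            if isinstance(e, PhaseShift) and not (0 <= e.shift < self.T):
                raise ParameterError(
                    f"phase shift must lie in [0, T), got {e.shift} with T={self.T}"
                )
        object.__setattr__(self, "events", events)

    @property
    def pulses(self) -> Tuple[Pulse, ...]:
        return tuple(e for e in self.events if isinstance(e, Pulse))

    @property
    def phase_shifts(self) -> Tuple[PhaseShift, ...]:
        return tuple(e for e in self.events if isinstance(e, PhaseShift))


def square_input(t, program: ForcingProgram):
    """Evaluate the input level I at time(s) ``t``.

    The base square wave is Imax on [0, T/2) of each (phase-adjusted)
    period and 0 on [T/2, T).  All PhaseShift events at or before t
    advance the effective time; Pulse events override the base wave with
    their amplitude during [start, start + duration).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    tp = t.copy()
    for ev in program.phase_shifts:
        tp = np.where(t >= ev.time, tp + ev.shift, tp)
    half = program.T / 2.0
    out = np.where(np.mod(tp, program.T) < half, program.Imax, 0.0)
    for ev in program.pulses:
        out = np.where((t >= ev.start) & (t < ev.end), ev.amplitude, out)
    return float(out[0]) if scalar else out


def forcing_breakpoints(program: ForcingProgram, t_end: float):
    """Times in [0, t_end] at which the input level can change, plus levels.

    Returns ``(times, levels)`` where ``times`` is a sorted array starting
    at 0 and ending at ``t_end`` and ``levels[i]`` is the constant input on
    ``[times[i], times[i+1])``.  Used by the exact stochastic simulation,
    whose propensities are piecewise constant between these times.
    """
    half = program.T / 2.0
    cuts = {0.0, float(t_end)}
    # Segment the axis by phase-shift events; within a segment the square
    # wave toggles at t = k*half - cumulative_shift.
    shift_times = [ev.time for ev in program.phase_shifts]
    seg_edges = [0.0] + [t for t in shift_times if 0.0 < t < t_end] + [float(t_end)]
    cum = 0.0
    shifts_iter = list(program.phase_shifts)
    for lo, hi in zip(seg_edges, seg_edges[1:]):
        cum = sum(ev.shift for ev in shifts_iter if ev.time <= lo)
        k_lo = int(np.floor((lo + cum) / half))
        k_hi = int(np.ceil((hi + cum) / half))
        for k in range(k_lo, k_hi + 1):
            t = k * half - cum
            if lo < t < hi:
                cuts.add(t)
        cuts.add(lo)
    for ev in program.pulses:
        for t in (ev.start, ev.end):
            if 0.0 < t < t_end:
                cuts.add(float(t))
    times = np.array(sorted(cuts))
    levels = square_input((times[:-1] + times[1:]) / 2.0, program)
    return times, np.atleast_1d(levels)


# ---------------------------------------------------------------------------
# Kim-Forger model
# ---------------------------------------------------------------------------


def repression(Z, A: float):
    """Repression rate f(Z, A): 1 - Z/A while Z/A <= 1, and 0 beyond.

    Piecewise-linear transcription rate, continuous at Z = A and bounded
    in [0, 1] for Z >= 0.  Scalar or array ``Z``.
    """
    if A <= 0:
        raise ParameterError(f"repression threshold A must be > 0, got {A}")
    Z = np.asarray(Z, dtype=float)
    out = np.where(Z / A <= 1.0, 1.0 - Z / A, 0.0)
    return float(out) if out.ndim == 0 else out


def kim_forger_drift(state, params: KimForgerParams, I: float = 0.0) -> np.ndarray:
    """Deterministic rates (dX, dY, dZ) of the scaled Kim-Forger model.

    tau * (f(Z, A) - X + I, X - Y, Y - Z) with tau = :data:`KF_TIME_SCALE`,
    so the free-running period is 1.
    """
    X, Y, Z = state
    tau = KF_TIME_SCALE
    return tau * np.array([repression(Z, params.A) - X + I, X - Y, Y - Z])


def kim_forger_diffusion(state, params: KimForgerParams, I: float = 0.0) -> np.ndarray:
    """Chemical-Langevin noise coefficients, one column per reaction channel.

    Returns a 3 x 7 matrix G whose row X is s*(sqrt(f), -sqrt(X), sqrt(I),
    0, 0, 0, 0), row Y is s*(0, 0, 0, sqrt(X), -sqrt(Y), 0, 0) and row
    Z is s*(0, 0, 0, 0, 0, sqrt(Y), -sqrt(Z)), with s = sigma *
    sqrt(KF_TIME_SCALE) (the time scaling acts on the propensities under
    the square roots); each channel carries an independent Wiener
    increment.  Square-root arguments are clamped at 0 (the caller's
    integrator counts clamp occurrences).
    """
    X, Y, Z = (float(v) for v in state)
    s = params.sigma
    f = repression(Z, params.A)
    Xc, Yc, Zc = max(X, 0.0), max(Y, 0.0), max(Z, 0.0)
    G = np.zeros((3, 7))
    if s > 0:
        st = s * np.sqrt(KF_TIME_SCALE)
        G[0, 0] = st * np.sqrt(f)
        G[0, 1] = -st * np.sqrt(Xc)
        G[0, 2] = st * np.sqrt(max(I, 0.0))
        G[1, 3] = st * np.sqrt(Xc)
        G[1, 4] = -st * np.sqrt(Yc)
        G[2, 5] = st * np.sqrt(Yc)
        G[2, 6] = -st * np.sqrt(Zc)
    return G


#: State-change vectors of the 7 elementary reactions over counts (x, y, z):
#: x-synthesis, x-decay, x-input, y-synthesis, y-decay, z-synthesis, z-decay.
KF_STOICHIOMETRY = np.array(
    [
        [1, 0, 0],
        [-1, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, -1, 0],
        [0, 0, 1],
        [0, 0, -1],
    ],
    dtype=np.int64,
)


def kim_forger_propensities(x, y, z, omega: float, A: float, I: float = 0.0) -> np.ndarray:
    """Reaction propensities of the discrete Kim-Forger scheme in counts.

    Rates are tau * [Omega*f(z/Omega, A), x, Omega*I, x, y, y, z] with
    tau = :data:`KF_TIME_SCALE`; equal to Omega times the corresponding
    concentration-space reaction terms at (x/Omega, y/Omega, z/Omega).
    """
    if omega <= 0:
        raise ParameterError(f"system size Omega must be > 0, got {omega}")
    return KF_TIME_SCALE * np.array(
        [
            omega * repression(z / omega, A),
            float(x),
            omega * max(I, 0.0),
            float(x),
            float(y),
            float(y),
            float(z),
        ]
    )


@dataclass(frozen=True)
class ReactionScheme:
    """Discrete reaction scheme: stoichiometry plus a propensity evaluator."""

    stoichiometry: np.ndarray
    propensities: Callable[..., np.ndarray]


def kim_forger_scheme() -> ReactionScheme:
    """The 7-reaction discrete counterpart of the Kim-Forger model."""
    return ReactionScheme(
        stoichiometry=KF_STOICHIOMETRY.copy(),
        propensities=kim_forger_propensities,
    )


# ---------------------------------------------------------------------------
# Van der Pol and amplitude-phase models
# ---------------------------------------------------------------------------


def vdp_drift(state, params: VanDerPolParams, I: float = 0.0) -> np.ndarray:
    """Deterministic rates (dX, dY) of the forced Van der Pol oscillator."""
    X, Y = state
    return np.array([Y, -(params.B * X * X - params.d) * Y - X + I])


def amplitude_phase_drift(state, params: AmplitudePhaseParams, I: float = 0.0) -> np.ndarray:
    """Deterministic rates (dX, dY) of the amplitude-phase oscillator."""
    X, Y = state
    R = np.hypot(X, Y)
    return np.array(
        [
            params.lam * X * (params.amp - R) - params.omega * Y + I,
            params.lam * Y * (params.amp - R) + params.omega * X,
        ]
    )


def drift_function(params: ModelParams) -> Callable:
    """Return the drift evaluator ``(state, I) -> rates`` for a parameter set."""
    if isinstance(params, KimForgerParams):
        return lambda state, I=0.0: kim_forger_drift(state, params, I)
    if isinstance(params, VanDerPolParams):
        return lambda state, I=0.0: vdp_drift(state, params, I)
    if isinstance(params, AmplitudePhaseParams):
        return lambda state, I=0.0: amplitude_phase_drift(state, params, I)
    raise ParameterError(f"unknown model parameter type {type(params)!r}")
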