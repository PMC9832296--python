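"""The four computational experiments.

1. Arnold-tongue scans: phase coherence (PC) over a grid of input
   periods and amplitudes, summarized by the grid-average PC, with
   sweeps over noise intensity, population size, fixed total volume and
   parameter heterogeneity.
2. Phase response curves (PRCs): cyclic phase shift of a population
   caused by a finite input pulse, as a function of the pulse phase.
3. Jet-lag recovery: per-day phase differences after a persistent phase
   shift of the input, and the day on which the population re-locks.
4. Van der Pol regime comparison: the noise sweep repeated for the
   limit-cycle and the damped (noise-induced) presets.

Every cell of every sweep derives its seed deterministically from the
master seed and the cell's grid coordinates, so single cells can be
recomputed in isolation, bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    AmplitudePhaseParams,
    ForcingProgram,
    KimForgerParams,
    ParameterError,
    PhaseShift,
    Pulse,
    VanDerPolParams,
    vdp_preset,
)
from .simulate import (
    SimConfig,
    SimulationError,
    Trajectory,
    euler_maruyama,
    simulate_population,
)
from . import metrics
from .metrics import (
    JetLagCurve,
    MetricError,
    circular_mean,
    detect_peaks,
    phase_coherence,
    population_phase_coherence,
    wrap_phase,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TongueGrid",
    "PRCTable",
    "VolumeSweep",
    "TongueAxes",
    "reference_period",
    "default_axes",
    "arnold_tongue",
    "noise_sweep",
    "fit_noise_optimum",
    "fixed_volume_sweep",
    "heterogeneity_sweep",
    "prc_experiment",
    "jetlag_experiment",
    "vdp_regime_comparison",
]


# ---------------------------------------------------------------------------
# Reference periods and grid axes
# ---------------------------------------------------------------------------

_PERIOD_CACHE: Dict[Tuple, float] = {}


def reference_period(params, dt: float = 0.001) -> float:
    """Deterministic free-running period of a model (measured, cached).

    For the damped (noise-induced) Van der Pol regime, which has no limit
    cycle, the period of the decaying ringing from a displaced start is
    used instead; it sets the natural timescale of the driven system.
    """
    from .simulate import _params_key  # shared cache key

    key = _params_key(params) + (dt,)
    if key in _PERIOD_CACHE:
        return _PERIOD_CACHE[key]
    quiet = ForcingProgram(T=1.0, Imax=0.0)
    det = _strip_noise(params)
    damped = isinstance(params, VanDerPolParams) and params.d < 0
    if damped:
        # ringdown from a displaced start; linear period ~ 2*pi
        cfg = SimConfig(dt=dt, t_end=80.0, seed=0, method="ode")
        traj = euler_maruyama(det, quiet, cfg, initial_state=np.array([1.0, 0.0]))
        period = metrics.free_running_period(traj, transient=0.0,
                                             min_prominence=0.01)
    else:
        guess = {"kim_forger": 1.0, "van_der_pol": 10.0, "amplitude_phase": 7.0}
        horizon = 40.0 * guess[params.kind]
        cfg = SimConfig(dt=dt, t_end=horizon, seed=0, method="ode")
        traj = euler_maruyama(det, quiet, cfg)
        period = metrics.free_running_period(
            traj, transient=horizon / 4, min_separation=0.4 * guess[params.kind])
    _PERIOD_CACHE[key] = period
    return period


def _strip_noise(params):
    if isinstance(params, KimForgerParams):
        return KimForgerParams(A=params.A, sigma=0.0)
    if isinstance(params, VanDerPolParams):
        return VanDerPolParams(d=params.d, B=params.B, sigma=0.0)
    return AmplitudePhaseParams(lam=params.lam, amp=params.amp,
                                omega=params.omega, sigma=0.0)


def _with_sigma(params, sigma: float):
    if isinstance(params, KimForgerParams):
        return KimForgerParams(A=params.A, sigma=sigma)
    if isinstance(params, VanDerPolParams):
        return VanDerPolParams(d=params.d, B=params.B, sigma=sigma)
    return AmplitudePhaseParams(lam=params.lam, amp=params.amp,
                                omega=params.omega, sigma=sigma)


#: Default top of the input-amplitude axis, per model kind, chosen so the
#: deterministic tongue closes inside the scanned rectangle.  Expressed in
#: the model's own input units.
_AMP_MAX = {"kim_forger": 0.1, "van_der_pol": 0.5, "amplitude_phase": 0.5}


@dataclass(frozen=True)
class TongueAxes:
    """Input-period and input-amplitude axes of an Arnold-tongue scan."""

    periods: np.ndarray
    amplitudes: np.ndarray


def default_axes(params, n_periods: int = 21, n_amplitudes: int = 21,
                 period_span: Tuple[float, float] = (0.7, 1.3),
                 amp_max: Optional[float] = None) -> TongueAxes:
    """Axes spanning period_span x free-running period and 0..amp_max."""
    ref = reference_period(params)
    if amp_max is None:
        amp_max = _AMP_MAX[params.kind]
    return TongueAxes(
        periods=ref * np.linspace(period_span[0], period_span[1], n_periods),
        amplitudes=np.linspace(0.0, amp_max, n_amplitudes),
    )


# ---------------------------------------------------------------------------
# Arnold tongue
# ---------------------------------------------------------------------------


@dataclass
class TongueGrid:
    """PC (and optionally PPC) over an (amplitude, period) grid."""

    periods: np.ndarray
    amplitudes: np.ndarray
    pc: np.ndarray  # (n_amplitudes, n_periods)
    ppc: Optional[np.ndarray] = None
    n: int = 1
    sigma: float = 0.0
    seed: int = 0

    @property
    def average_pc(self) -> float:
        """Grid-average PC; missing (failed) cells are excluded."""
        return float(np.nanmean(self.pc))

    @property
    def average_ppc(self) -> Optional[float]:
        if self.ppc is None:
            return None
        return float(np.nanmean(self.ppc))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ia, a in enumerate(self.amplitudes):
            for ip, T in enumerate(self.periods):
                row = {"Imax": a, "T": T, "pc": self.pc[ia, ip]}
                if self.ppc is not None:
                    row["ppc"] = self.ppc[ia, ip]
                rows.append(row)
        return pd.DataFrame(rows)


def cell_seed(master_seed: int, i_amp: int, i_per: int, replicate: int = 0) -> int:
    """Deterministic per-cell master seed; stable under scan order."""
    ss = np.random.SeedSequence([int(master_seed), 7, int(i_amp), int(i_per),
                                 int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def tongue_cell(params, T: float, Imax: float, config: SimConfig,
                member_A=None, compute_ppc: bool = False,
                transient_cycles: int = 10, measure_cycles: int = 20,
                min_prominence: float = 0.1):
    """PC (and optionally PPC) of one forcing cell.

    Simulates the population for transient_cycles + measure_cycles input
    cycles, detects peaks of the population mean (and of each member for
    PPC) and evaluates the phase metrics on the post-transient span.
    """
    forcing = ForcingProgram(T=T, Imax=Imax)
    t_trans = transient_cycles * T
    # one padding cycle so the last analyzed peak keeps its full prominence
    t_end = (transient_cycles + measure_cycles + 1) * T
    cfg = replace(config, t_end=t_end, transient=t_trans,
                  record_members=compute_ppc)
    pop = simulate_population(params, forcing, cfg, member_A=member_A)
    peaks = detect_peaks(pop.mean_trajectory, min_separation=0.5 * T,
                         min_prominence=min_prominence, t_start=t_trans)
    pc = phase_coherence(peaks, T, t_trans, measure_cycles)
    ppc = None
    if compute_ppc:
        times = pop.mean_trajectory.times
        member_peaks = [
            detect_peaks((times, row), min_separation=0.5 * T,
                         min_prominence=min_prominence, t_start=t_trans)
            for row in pop.member_outputs
        ]
        pop.member_peaks = member_peaks
        try:
            ppc = population_phase_coherence(member_peaks, T, t_trans,
                                             measure_cycles)
        except MetricError:
            ppc = np.nan
    return pc, ppc


def arnold_tongue(params, axes: Optional[TongueAxes] = None, n: int = 1,
                  sigma: Optional[float] = None, seed: int = 0,
                  config: Optional[SimConfig] = None,
                  compute_ppc: bool = False,
                  transient_cycles: int = 10, measure_cycles: int = 20,
                  member_A=None) -> TongueGrid:
    """Scan PC over an (input period, input amplitude) grid.

    ``sigma`` overrides the noise intensity of ``params`` when given; the
    integration method resolves automatically per cell (exact SSA below
    system size 1000).  Failed cells are recorded as NaN and excluded
    from the average with a warning.
    """
    if sigma is not None:
        params = _with_sigma(params, sigma)
    if axes is None:
        axes = default_axes(params)
    base = config or SimConfig()
    pc = np.full((len(axes.amplitudes), len(axes.periods)), np.nan)
    ppc = np.full_like(pc, np.nan) if compute_ppc else None
    for ia, a in enumerate(axes.amplitudes):
        for ip, T in enumerate(axes.periods):
            cfg = replace(base, seed=cell_seed(seed, ia, ip), n=n)
            try:
                c_pc, c_ppc = tongue_cell(
                    params, float(T), float(a), cfg, member_A=member_A,
                    compute_ppc=compute_ppc,
                    transient_cycles=transient_cycles,
                    measure_cycles=measure_cycles)
            except (SimulationError, MetricError) as exc:
                logger.warning("tongue cell (Imax=%.4g, T=%.4g) failed: %s",
                               a, T, exc)
                continue
            pc[ia, ip] = c_pc
            if compute_ppc:
                ppc[ia, ip] = c_ppc
    return TongueGrid(periods=axes.periods, amplitudes=axes.amplitudes,
                      pc=pc, ppc=ppc, n=n, sigma=params.sigma, seed=seed)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def noise_sweep(params, n_values: Sequence[int], sigma_values: Sequence[float],
                axes: Optional[TongueAxes] = None, seed: int = 0,
                n_seeds: int = 1, compute_ppc: bool = False,
                config: Optional[SimConfig] = None,
                transient_cycles: int = 10,
                measure_cycles: int = 20) -> pd.DataFrame:
    """Grid-average PC (and PPC) per (population size, noise intensity).

    Returns one row per (n, sigma, seed replicate).  Use
    :func:`fit_noise_optimum` for the second-order polynomial summary of
    the sigma dependence.
    """
    if axes is None:
        axes = default_axes(params)
    rows = []
    for n in n_values:
        for sigma in sigma_values:
            for rep in range(n_seeds):
                grid = arnold_tongue(
                    params, axes=axes, n=int(n), sigma=float(sigma),
                    seed=int(np.random.SeedSequence([seed, rep]).generate_state(
                        1, dtype=np.uint32)[0]),
                    config=config, compute_ppc=compute_ppc,
                    transient_cycles=transient_cycles,
                    measure_cycles=measure_cycles)
                rows.append({
                    "n": int(n), "sigma": float(sigma), "replicate": rep,
                    "average_pc": grid.average_pc,
                    "average_ppc": grid.average_ppc,
                })
    return pd.DataFrame(rows)


def fit_noise_optimum(sweep: pd.DataFrame, n: int) -> Dict[str, float]:
    """Second-order polynomial fit of average PC against sigma for one n.

    Returns the coefficients and the fitted optimum (vertex) when it is a
    maximum; a smooth one-number summary of where the noise benefit peaks.
    """
    sub = sweep[sweep["n"] == n].groupby("sigma")["average_pc"].mean()
    s = sub.index.to_numpy(dtype=float)
    y = sub.to_numpy(dtype=float)
    if s.size < 3:
        raise ParameterError("need at least 3 sigma values to fit a parabola")
    c2, c1, c0 = np.polyfit(s, y, 2)
    out = {"c2": c2, "c1": c1, "c0": c0}
    if c2 < 0:
        out["sigma_opt"] = -c1 / (2 * c2)
        out["pc_opt"] = c0 - c1 * c1 / (4 * c2)
    return out


@dataclass
class VolumeSweep:
    """Average PC when a fixed total volume V is split into n cells."""

    table: pd.DataFrame  # columns: V, n, omega, sigma, method, average_pc

    def argmax_n(self, V: float) -> int:
        sub = self.table[self.table["V"] == V]
        return int(sub.loc[sub["average_pc"].idxmax(), "n"])


def fixed_volume_sweep(params, V_values: Sequence[float],
                       n_values: Sequence[int],
                       axes: Optional[TongueAxes] = None, seed: int = 0,
                       config: Optional[SimConfig] = None,
                       transient_cycles: int = 10,
                       measure_cycles: int = 20) -> VolumeSweep:
    """Split total system size V into n cells of size Omega = V/n each.

    Per cell sigma = (V/n)^(-1/2); the integrator switches to the exact
    SSA automatically once Omega < 1000.
    """
    if not isinstance(params, KimForgerParams):
        raise ParameterError("the fixed-volume sweep is defined for the "
                             "Kim-Forger model (sigma derives from Omega)")
    if axes is None:
        axes = default_axes(params)
    from .simulate import select_method

    rows = []
    for V in V_values:
        for n in n_values:
            omega = float(V) / int(n)
            p = KimForgerParams(A=params.A, omega_size=omega)
            grid = arnold_tongue(
                p, axes=axes, n=int(n), seed=int(np.random.SeedSequence(
                    [seed, int(V), int(n)]).generate_state(1, dtype=np.uint32)[0]),
                config=config, transient_cycles=transient_cycles,
                measure_cycles=measure_cycles)
            rows.append({
                "V": float(V), "n": int(n), "omega": omega,
                "sigma": p.sigma, "method": select_method(omega=omega),
                "average_pc": grid.average_pc,
            })
    return VolumeSweep(table=pd.DataFrame(rows))


def heterogeneity_sweep(params, sigma_A_values: Sequence[float], n: int = 1000,
                        axes: Optional[TongueAxes] = None, seed: int = 0,
                        config: Optional[SimConfig] = None,
                        transient_cycles: int = 10,
                        measure_cycles: int = 20):
    """Deterministic members with repression thresholds A_i ~ N(A0, sigma_A).

    Models cell-to-cell variability instead of intrinsic noise: each
    member is noiseless but has its own parameter drawn from a normal
    distribution truncated to positive values (non-positive draws are
    re-sampled and counted).  Returns (table, samples) where samples maps
    sigma_A to the member parameter draw used.
    """
    if not isinstance(params, KimForgerParams):
        raise ParameterError("heterogeneity applies to the Kim-Forger threshold A")
    if axes is None:
        axes = default_axes(params)
    det = _strip_noise(params)
    rows = []
    samples: Dict[float, np.ndarray] = {}
    for sigma_A in sigma_A_values:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, 11, int(round(1e9 * sigma_A))]))
        if sigma_A == 0:
            draw = np.full(n, params.A)
            resampled = 0
        else:
            draw = rng.normal(params.A, sigma_A, size=n)
            resampled = 0
            bad = draw <= 0
            while np.any(bad):
                resampled += int(bad.sum())
                draw[bad] = rng.normal(params.A, sigma_A, size=int(bad.sum()))
                bad = draw <= 0
        if resampled:
            logger.info("sigma_A=%g: re-sampled %d non-positive draws",
                        sigma_A, resampled)
        samples[float(sigma_A)] = draw
        grid = arnold_tongue(det, axes=axes, n=n, seed=seed, config=config,
                             transient_cycles=transient_cycles,
                             measure_cycles=measure_cycles, member_A=draw)
        rows.append({"sigma_A": float(sigma_A), "n": n,
                     "average_pc": grid.average_pc,
                     "resampled_draws": resampled})
    return pd.DataFrame(rows), samples


# ---------------------------------------------------------------------------
# Phase response curves
# ---------------------------------------------------------------------------


@dataclass
class PRCTable:
    """Phase response curve: cyclic shift vs cyclic pulse time.

    Phases and shifts are cycle fractions on the unit circle (shift in
    (-0.5, 0.5]).  ``amplitude`` is max |mean shift|, the continuous
    counterpart of the visual type-1 / type-0 classification: values
    approaching 0.5 indicate a type-0 (large, visually discontinuous)
    response.
    """

    pulse_phases: np.ndarray
    mean_shift: np.ndarray  # cycles
    sd_shift: np.ndarray  # cycles
    pulse_amplitude: float
    pulse_duration: float
    n_replicates: int

    @property
    def amplitude(self) -> float:
        return float(np.max(np.abs(self.mean_shift)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pulse_phase": self.pulse_phases,
            "mean_shift": self.mean_shift,
            "sd_shift": self.sd_shift,
        })


def _population_phase(pop_mean: Trajectory, period: float, t_from: float,
                      n_cycles: int) -> float:
    """Circular-mean peak phase (radians, mod period) over late cycles."""
    peaks = detect_peaks(pop_mean, min_separation=0.5 * period,
                         t_start=t_from)
    sel = peaks.times[peaks.times >= t_from]
    if sel.size == 0:
        raise MetricError("no peaks in the phase-measurement window")
    sel = sel[-n_cycles:] if sel.size > n_cycles else sel
    return circular_mean(2 * np.pi * np.mod(sel, period) / period)


def prc_experiment(params, I: float, n: int = 100,
                   pulse_duration: float = 0.5, n_phases: int = 8,
                   replicates: int = 10, seed: int = 0,
                   config: Optional[SimConfig] = None,
                   baseline_Imax: float = 0.0,
                   measure_cycles: int = 5) -> PRCTable:
    """Phase response of a free-running population to a single pulse.

    The baseline is a free-running (dark) population by default
    (``baseline_Imax`` sets a constant-pacing square wave instead).  For
    each of ``n_phases`` equally spaced cyclic pulse times, a pulse of
    the given amplitude and duration is applied after a 10-period
    transient, and the phase shift is the cyclic difference between the
    perturbed and an unperturbed reference population simulated with the
    identical seeds.  Shifts are reported as cycle fractions in
    (-0.5, 0.5], mean and sd over replicates.
    """
    period = reference_period(params)
    base = config or SimConfig()
    t_trans = 10.0 * period
    settle = 10.0 * period
    phases = np.arange(n_phases) / n_phases
    shifts = np.full((n_phases, replicates), np.nan)
    forcing_base = ForcingProgram(T=period, Imax=baseline_Imax)
    for rep in range(replicates):
        rep_seed = int(np.random.SeedSequence([seed, 13, rep]).generate_state(
            1, dtype=np.uint32)[0])
        for iph, ph in enumerate(phases):
            t_pulse = t_trans + ph * period
            t_end = (t_pulse + pulse_duration + settle
                     + (measure_cycles + 1) * period)
            cfg = replace(base, seed=rep_seed, n=n, t_end=t_end,
                          transient=t_trans)
            pulse = Pulse(start=t_pulse, duration=pulse_duration, amplitude=I)
            forcing_pulse = ForcingProgram(T=period, Imax=baseline_Imax,
                                           events=(pulse,))
            t_from = t_pulse + pulse_duration + settle
            try:
                ref = simulate_population(params, forcing_base, cfg)
                per = simulate_population(params, forcing_pulse, cfg)
                phi_ref = _population_phase(ref.mean_trajectory, period,
                                            t_from, measure_cycles)
                phi_per = _population_phase(per.mean_trajectory, period,
                                            t_from, measure_cycles)
            except (MetricError, SimulationError) as exc:
                logger.warning("PRC replicate %d phase %.3f dropped: %s",
                               rep, ph, exc)
                continue
            shifts[iph, rep] = wrap_phase(phi_per - phi_ref) / (2 * np.pi)
    mean = np.full(n_phases, np.nan)
    sd = np.full(n_phases, np.nan)
    for iph in range(n_phases):
        vals = shifts[iph][~np.isnan(shifts[iph])]
        if vals.size == 0:
            continue
        ang = 2 * np.pi * vals
        mean[iph] = wrap_phase(circular_mean(ang)) / (2 * np.pi)
        R = min(1.0, abs(np.exp(1j * ang).mean()))
        sd[iph] = (np.sqrt(max(0.0, -2.0 * np.log(R))) / (2 * np.pi)
                   if R > 0 else 0.5)
    return PRCTable(pulse_phases=phases, mean_shift=mean, sd_shift=sd,
                    pulse_amplitude=I, pulse_duration=pulse_duration,
                    n_replicates=replicates)


# ---------------------------------------------------------------------------
# Jet lag
# ---------------------------------------------------------------------------


@dataclass
class JetLagResult:
    """Replicate-aggregated jet-lag recovery."""

    day_index: np.ndarray
    mean_difference: np.ndarray  # radians, circular mean across replicates
    sd_difference: np.ndarray
    recovery_days: np.ndarray  # one per replicate (NaN = not recovered)
    shift: float
    T: float

    @property
    def mean_recovery_day(self) -> float:
        ok = self.recovery_days[~np.isnan(self.recovery_days)]
        return float(ok.mean()) if ok.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.day_index,
            "mean_phase_difference": self.mean_difference,
            "sd_phase_difference": self.sd_difference,
        })


def _recovery_day(curve: JetLagCurve, tol: float = 0.1 * 2 * np.pi,
                  consecutive: int = 3) -> float:
    """First post-shift day from which the phase stays within ``tol`` of
    the final locked phase for ``consecutive`` days."""
    post = curve.day_index >= 0
    days = curve.day_index[post]
    diffs = curve.phase_difference[post]
    good = ~np.isnan(diffs)
    if good.sum() < consecutive:
        return float("nan")
    locked = circular_mean(diffs[good][-consecutive:])
    dev = np.abs(wrap_phase(diffs - locked))
    ok = (dev <= tol) & good
    run = 0
    for i in range(len(days)):
        run = run + 1 if ok[i] else 0
        if run >= consecutive:
            return float(days[i - consecutive + 1])
    return float("nan")


def jetlag_experiment(params, I: float, T: float, shift: float,
                      n: int = 100, replicates: int = 10, seed: int = 0,
                      config: Optional[SimConfig] = None,
                      pre_cycles: int = 15, post_cycles: int = 25,
                      n_baseline_days: int = 5,
                      lock_threshold: float = 0.5,
                      recovery_tol: float = 0.1 * 2 * np.pi) -> JetLagResult:
    """Re-entrainment after a persistent phase shift of the input.

    The population entrains for ``pre_cycles`` input cycles, then the
    input phase advances by ``shift`` (persistently).  Per replicate the
    daily phase differences against the pre-shift baseline are computed,
    and the recovery day is the first day after which the phase stays
    within ``recovery_tol`` of the new locked phase for 3 consecutive
    days.  Replicates whose pre-shift baseline is not phase-locked
    (baseline resultant length below ``lock_threshold``) raise an error.
    """
    base = config or SimConfig()
    t_shift = pre_cycles * T
    # one padding cycle so the final day's peak keeps its full prominence
    t_end = t_shift + (post_cycles + 1) * T
    forcing = ForcingProgram(T=T, Imax=I,
                             events=(PhaseShift(time=t_shift, shift=shift % T),))
    n_days = n_baseline_days + post_cycles
    all_diffs = np.full((replicates, n_days), np.nan)
    rec = np.full(replicates, np.nan)
    day_index = None
    for rep in range(replicates):
        rep_seed = int(np.random.SeedSequence([seed, 17, rep]).generate_state(
            1, dtype=np.uint32)[0])
        cfg = replace(base, seed=rep_seed, n=n, t_end=t_end,
                      transient=(pre_cycles - n_baseline_days) * T)
        pop = simulate_population(params, forcing, cfg)
        peaks = detect_peaks(pop.mean_trajectory, min_separation=0.5 * T,
                             t_start=(pre_cycles - n_baseline_days) * T)
        curve = metrics.jetlag_phase_differences(
            peaks, T, t_shift, n_baseline_days=n_baseline_days,
            n_post_days=post_cycles)
        basep = curve.phase_difference[curve.day_index < 0]
        basep = basep[~np.isnan(basep)]
        if basep.size == 0 or abs(np.exp(1j * basep).mean()) < lock_threshold:
            raise SimulationError(
                f"replicate {rep}: population not phase-locked before the shift"
            )
        all_diffs[rep, :] = curve.phase_difference
        rec[rep] = _recovery_day(curve, tol=recovery_tol)
        day_index = curve.day_index
    mean = np.full(n_days, np.nan)
    sd = np.full(n_days, np.nan)
    for d in range(n_days):
        vals = all_diffs[:, d]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        mean[d] = wrap_phase(circular_mean(vals))
        R = min(1.0, abs(np.exp(1j * vals).mean()))
        sd[d] = np.sqrt(max(0.0, -2.0 * np.log(R))) if R > 0 else np.pi
    return JetLagResult(day_index=day_index, mean_difference=mean,
                        sd_difference=sd, recovery_days=rec,
                        shift=shift, T=T)


# ---------------------------------------------------------------------------
# Van der Pol regime comparison
# ---------------------------------------------------------------------------


def vdp_regime_comparison(sigma_values: Sequence[float],
                          n_values: Sequence[int] = (100,),
                          axes_kwargs: Optional[dict] = None, seed: int = 0,
                          n_seeds: int = 1,
                          config: Optional[SimConfig] = None,
                          transient_cycles: int = 5,
                          measure_cycles: int = 10) -> Dict[str, pd.DataFrame]:
    """Noise sweeps for the limit-cycle and noise-induced Van der Pol presets.

    The deterministic (sigma = 0) reference must be part of
    ``sigma_values``.  Grid axes are scaled to each regime's own natural
    period.  Returns {'limit_cycle': table, 'noise_induced': table}.
    """
    out = {}
    for name in ("limit_cycle", "noise_induced"):
        params = vdp_preset(name)
        axes = default_axes(params, **(axes_kwargs or {}))
        out[name] = noise_sweep(params, n_values, sigma_values, axes=axes,
                                seed=seed, n_seeds=n_seeds, config=config,
                                transient_cycles=transient_cycles,
                                measure_cycles=measure_cycles)
    return out
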