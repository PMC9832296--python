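"""Peak-based phase metrics of entrainment.

All phase quantities are built from peak times of an oscillatory signal.
The phase of a peak at time t relative to an input of period T is the
cycle fraction mapped to the unit circle, 2*pi*((t mod T)/T).  Two
population statistics follow:

* phase coherence (PC): the resultant length of the population-mean
  signal's peak phases across N input cycles -- 1 when the averaged
  signal peaks at the same cycle phase every cycle, near 0 when peaks
  wander (no entrainment) or cycles go peakless (amplitude collapse,
  which still counts toward N).
* population phase coherence (PPC): the Kuramoto order parameter of the
  individual members' peak phases within one cycle, averaged (resultant
  lengths) over cycles -- 1 for a fully synchronized population, near 0
  for a dispersed one.

Jet-lag recovery is tracked as the signed cyclic difference between each
day's peak phase and the pre-shift baseline phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulate import Trajectory

__all__ = [
    "PeakSeries",
    "JetLagCurve",
    "MetricError",
    "detect_peaks",
    "cycle_phase",
    "order_parameter",
    "circular_mean",
    "wrap_phase",
    "phase_coherence",
    "population_phase_coherence",
    "jetlag_phase_differences",
    "free_running_period",
]


class MetricError(ValueError):
    """A metric is undefined for the given input."""


@dataclass(frozen=True)
class PeakSeries:
    """Ordered local-maximum times (and heights) of one signal.

    May be empty, which flags a non-oscillatory signal.
    """

    times: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        if t.shape != h.shape:
            raise MetricError("peak times and heights must align")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise MetricError("peak times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class JetLagCurve:
    """Per-day cyclic phase differences relative to a pre-shift baseline."""

    day_index: np.ndarray  # integer cycle index relative to the shift
    phase_difference: np.ndarray  # radians in (-pi, pi]; NaN where no peak
    baseline_phase: float
    sd: Optional[np.ndarray] = None  # across replicates, when aggregated


def detect_peaks(trajectory_or_signal, min_separation: float,
                 min_prominence: float = 0.1, var: int = 0,
                 t_start: float = 0.0) -> PeakSeries:
    """Local maxima of a uniformly sampled signal, filtered by separation
    and prominence.

    min_separation is a time (typically half the input period);
    min_prominence is a fraction of the signal range on the analyzed
    span.  Analysis starts at ``t_start`` (transient discard).  A
    constant signal yields an empty series rather than an error.
    """
    if isinstance(trajectory_or_signal, Trajectory):
        times = trajectory_or_signal.times
        x = trajectory_or_signal.output(var)
    else:
        times, x = trajectory_or_signal
        times = np.asarray(times, dtype=float)
        x = np.asarray(x, dtype=float)
    if times.size < 3:
        return PeakSeries(np.empty(0), np.empty(0))
    dt = times[1] - times[0]
    i0 = int(np.searchsorted(times, t_start, side="left"))
    xs = x[i0:]
    if xs.size < 3:
        return PeakSeries(np.empty(0), np.empty(0))
    rng = float(np.max(xs) - np.min(xs))
    if rng == 0.0:
        return PeakSeries(np.empty(0), np.empty(0))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(xs, distance=distance, prominence=min_prominence * rng)
    return PeakSeries(times[i0:][idx], xs[idx])


def cycle_phase(peak_time, T: float):
    """Map a peak time to the unit circle: 2*pi*((t mod T)/T)."""
    if T <= 0:
        raise MetricError(f"period T must be > 0, got {T}")
    return 2.0 * np.pi * (np.mod(peak_time, T) / T)


def order_parameter(angles) -> tuple:
    """Kuramoto order parameter: r*exp(i*psi) = mean of exp(i*phi_j).

    Returns (r, psi) with r in [0, 1] and psi in [0, 2*pi).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise MetricError("order parameter undefined for an empty phase sample")
    zbar = np.exp(1j * angles).mean()
    r = abs(zbar)
    psi = float(np.mod(np.angle(zbar), 2.0 * np.pi))
    return float(r), psi


def circular_mean(angles) -> float:
    """Mean direction of angles (radians), in [0, 2*pi)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise MetricError("circular mean undefined for an empty sample")
    zbar = np.exp(1j * angles).mean()
    return float(np.mod(np.angle(zbar), 2.0 * np.pi))


def wrap_phase(delta):
    """Wrap angle differences to (-pi, pi], ties at pi resolved positive."""
    delta = np.asarray(delta, dtype=float)
    out = -(np.mod(-delta + np.pi, 2.0 * np.pi) - np.pi)
    return float(out) if out.ndim == 0 else out


def _cycle_peak_phases(peaks: PeakSeries, T: float, t_start: float,
                       n_cycles: int) -> np.ndarray:
    """One phase per input cycle (highest peak wins); NaN for peakless cycles."""
    phases = np.full(n_cycles, np.nan)
    if len(peaks) == 0:
        return phases
    k = np.floor((peaks.times - t_start) / T).astype(int)
    ok = (k >= 0) & (k < n_cycles)
    for cyc in np.unique(k[ok]):
        sel = np.nonzero(k == cyc)[0]
        best = sel[np.argmax(peaks.heights[sel])]
        phases[cyc] = cycle_phase(peaks.times[best], T)
    return phases


def phase_coherence(population_peaks: PeakSeries, T: float, t_start: float,
                    n_cycles: int) -> float:
    """PC = |(1/N) sum_k exp(i*phi_k)| over N input cycles.

    phi_k is the phase of the (highest) population-mean peak in cycle k,
    counted from ``t_start``.  Cycles without a peak contribute nothing
    to the sum but still count in N, so amplitude collapse is penalized.
    """
    if n_cycles < 1:
        raise MetricError("phase coherence needs at least one input cycle")
    phases = _cycle_peak_phases(population_peaks, T, t_start, n_cycles)
    good = ~np.isnan(phases)
    if not np.any(good):
        return 0.0
    return float(abs(np.exp(1j * phases[good]).sum()) / n_cycles)


def population_phase_coherence(member_peaks: Sequence[PeakSeries], T: float,
                               t_start: float, n_cycles: int,
                               combine: str = "mean_r") -> float:
    """PPC: per-cycle order parameter of member peak phases, averaged over cycles.

    Members without a peak in a cycle are excluded from that cycle's
    sum; cycles where no member peaks are skipped.  ``combine='mean_r'``
    (default) averages the per-cycle resultant lengths, whose collective
    phases generally differ across cycles; ``combine='complex'`` instead
    averages the per-cycle complex sums before taking the magnitude.
    """
    if len(member_peaks) == 0:
        raise MetricError("PPC needs at least one member")
    if combine not in ("mean_r", "complex"):
        raise MetricError(f"unknown combine mode {combine!r}")
    per_member = np.stack([
        _cycle_peak_phases(p, T, t_start, n_cycles) for p in member_peaks
    ])  # (n, n_cycles)
    r_vals: List[float] = []
    z_vals: List[complex] = []
    for c in range(n_cycles):
        col = per_member[:, c]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        z = np.exp(1j * col).mean()
        r_vals.append(abs(z))
        z_vals.append(z)
    if not r_vals:
        raise MetricError("no cycle had any member peak")
    if combine == "mean_r":
        return float(np.mean(r_vals))
    return float(abs(np.mean(z_vals)))


def jetlag_phase_differences(population_peaks: PeakSeries, T: float,
                             shift_event_time: float,
                             n_baseline_days: int = 5,
                             n_post_days: Optional[int] = None) -> JetLagCurve:
    """Daily phase differences around a persistent input phase shift.

    Day d covers [shift_time + d*T, shift_time + (d+1)*T); negative d are
    pre-shift.  The baseline is the circular mean of the ``n_baseline_days``
    phases immediately before the shift; each day's difference is the
    signed cyclic deviation from it, in (-pi, pi].  Days without a peak
    are marked NaN.
    """
    if n_baseline_days < 1:
        raise MetricError("need at least one baseline day")
    t0 = shift_event_time - n_baseline_days * T
    if t0 < -1e-9:
        raise MetricError(
            f"not enough pre-shift span for {n_baseline_days} baseline days"
        )
    last_peak = population_peaks.times[-1] if len(population_peaks) else shift_event_time
    if n_post_days is None:
        n_post_days = max(0, int(np.floor((last_peak - shift_event_time) / T)))
    n_days = n_baseline_days + n_post_days
    phases = _cycle_peak_phases(population_peaks, T, t0, n_days)
    base = phases[:n_baseline_days]
    base = base[~np.isnan(base)]
    if base.size == 0:
        raise MetricError("no peaks detected in the baseline window")
    baseline = circular_mean(base)
    diffs = wrap_phase(phases - baseline)
    diffs = np.where(np.isnan(phases), np.nan, diffs)
    days = np.arange(-n_baseline_days, n_post_days)
    return JetLagCurve(day_index=days, phase_difference=diffs,
                       baseline_phase=baseline)


def free_running_period(trajectory: Trajectory, transient: float = 0.0,
                        min_separation: Optional[float] = None,
                        min_prominence: float = 0.1, var: int = 0) -> float:
    """Mean peak-to-peak interval of an unforced signal after transient."""
    if min_separation is None:
        # generic guard against sampling jitter: a tenth of the span per peak
        span = trajectory.times[-1] - transient
        min_separation = max(trajectory.dt * 10, span * 0.01)
    peaks = detect_peaks(trajectory, min_separation=min_separation,
                         min_prominence=min_prominence, var=var,
                         t_start=transient)
    if len(peaks) < 3:
        raise MetricError(
            f"need at least 3 peaks to estimate a period, found {len(peaks)}"
        )
    return float(np.mean(np.diff(peaks.times)))
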