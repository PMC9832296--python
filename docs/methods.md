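# Methods

## Models

`oscent` simulates populations of *uncoupled* stochastic oscillators
driven by a shared periodic input, and quantifies entrainment at the
population level.  Three oscillator models are provided.

### Minimal clock model (`kim_forger`)

A three-variable negative feedback loop in scaled concentration units,

    dX/dt = tau * ( f(Z, A) - X + I )
    dY/dt = tau * ( X - Y )
    dZ/dt = tau * ( Y - Z )
    f(Z, A) = max(0, 1 - Z/A)

with a single free parameter `A` (repression threshold, default 0.1,
which gives high-amplitude limit-cycle oscillations while keeping X
clear of zero under moderate noise) and additive input `I` (light).
`tau = 3.6597` is a fixed time-scale constant: the unscaled loop with
`A = 0.1` has a natural period of 3.6597 (estimated by Richardson
extrapolation of fixed-step runs to zero step size), so with `tau`
folded into every rate the deterministic free-running period is 1.
All reported times are therefore in units of the free-running period.

Each of the seven additive terms above is an elementary reaction.  In a
cell of system size `Omega` (molecule count scale, `x = Omega*X` ...),
the reactions have propensities `tau * [Omega*f, x, Omega*I, x, y, y, z]`
and unit stoichiometries.  Two stochastic descriptions follow:

* **Chemical Langevin equation (CLE):** one independent Wiener channel
  per reaction with amplitude `sigma * sqrt(tau * rate)`, where
  `sigma = Omega^(-1/2)`.  The exponent is kept as a module constant
  (`SIGMA_OMEGA_EXPONENT`).  `sigma = 0.005` corresponds to
  `Omega = 40 000` molecules.
* **Exact Gillespie simulation (SSA)** of the discrete scheme, used
  automatically when `Omega < 1000` (`sigma > 0.032`), where the CLE
  becomes unreliable.

### Van der Pol (`van_der_pol`)

`dX = Y dt + sigma dW1`, `dY = [-(B X^2 - d) Y - X + I] dt + sigma dW2`.
Two named presets: `limit_cycle` (d=2, B=10; relaxation oscillations,
free period ~7.64) and `noise_induced` (d=-0.1, B=1; a damped focus
that oscillates sustainably only under noise; ringdown period ~6.30).
Noise here is generic additive disturbance, not molecular noise.

### Amplitude-phase (`amplitude_phase`)

A sinusoidal (lambda-omega) oscillator with radial relaxation rate
`lam`, amplitude `amp` and angular frequency `omega` (defaults all 1,
free period 2*pi), additive noise, input added to X.

## Forcing

The input is a square wave: `I = Imax` on the first half of each period
`T`, `0` on the second half.  Two event types modify it: a `Pulse`
overrides the signal with its own amplitude for a finite window, and a
`PhaseShift` advances the input phase persistently (jet lag).  The
input is evaluated at the left endpoint of each integration step; the
SSA receives it as breakpoint times with piecewise-constant levels and
rejects candidate reaction times that overshoot the next breakpoint,
which is exact for this input class.

## Integration

* Euler-Maruyama with fixed step `dt = 0.001` (in free-running-period
  units).  The deterministic (`sigma = 0`) path is seed-independent; a
  fixed-step cross-check against an adaptive solver (LSODA) is part of
  the test suite.
* Standard-normal increments are pre-generated with NumPy PCG64
  streams, one stream per population member keyed by
  `(master_seed, member_index)`, so any run is bit-reproducible from
  its seed and populations of different sizes share their leading
  members.  Inside the integrator the seven CLE channels are combined
  into one increment per state variable with variance equal to the sum
  of the channel variances (`f + X + I`, `X + Y`, `Y + Z`, times
  `sigma^2 tau dt`); this is distributionally identical because each
  Wiener channel enters exactly one variable, and cuts the random
  number budget by half.
* Negative concentrations can occur under the CLE; square-root
  arguments are clamped at zero and every clamp is counted in the
  trajectory metadata.  An optional `state_floor` aborts a trajectory
  that falls below a configured level (disabled by default: with the
  automatic method switch the CLE only runs at `sigma < 0.032`, where
  X stays positive in practice).
* SSA output is resampled onto the uniform grid by last observation
  carried forward (the jump process is right-continuous).

All population members start from the same point on the deterministic
attractor (obtained by a 50-period zero-noise burn-in), so
desynchronization emerges from noise alone.  The first 10 input cycles
of every analysis run are discarded as transient.

## Entrainment metrics

Peaks of a signal are local maxima passing a minimum separation (half
the input period) and a minimum prominence (10% of the signal range on
the analyzed span), found with `scipy.signal.find_peaks`.  Every
analysis simulation is padded by one extra input cycle past the last
analyzed one so the final peak keeps its full prominence.

The phase of a peak at time `t` is `2*pi*(t mod T)/T`.  With the
Kuramoto order parameter `r e^{i psi} = mean(e^{i phi_j})`:

* **PC (phase coherence)** - `|mean_k e^{i phi_k}|` over `N` input
  cycles, where `phi_k` is the phase of the population-mean peak in
  cycle `k`.  If a cycle contains several peaks the highest one is
  used (one phase per cycle); a cycle with no detected peak contributes
  nothing to the sum but still counts in `N`, so amplitude collapse is
  penalized.  PC measures population-level entrainment.
* **PPC (population phase coherence)** - the per-cycle `r` over the
  individual members' peak phases, averaged (resultant lengths) over
  cycles; members without a peak in a cycle are dropped from that
  cycle.  Averaging magnitudes rather than complex sums is the default
  because the collective phase differs across cycles; the complex
  variant is available as an option.  PPC measures synchrony *within*
  the population.
* **Jet lag** - daily peak phases before and after a persistent input
  phase shift, expressed as signed cyclic differences in `(-pi, pi]`
  from the circular-mean baseline of the last 5 pre-shift days.  The
  *recovery day* is the first post-shift day from which the phase stays
  within 0.1 cycles of the final locked phase for 3 consecutive days.
* **PRC** - for each of several equally spaced cyclic pulse times, the
  cyclic difference between the late-time peak phases of a pulsed
  population and an unpulsed reference simulated with identical noise
  streams, in cycle fractions in `(-0.5, 0.5]`; mean and circular sd
  over seed replicates.  The PRC amplitude (max |mean shift|) is
  reported as a continuous quantity; values approaching 0.5 correspond
  to the visually discontinuous "type 0" regime, small values to
  "type 1".  The pulse baseline is a free-running (dark) population by
  default; a constant-pacing baseline is available via
  `baseline_Imax`.

## Experiments and their default scales

* **Arnold tongue**: PC on a grid of input periods (0.7-1.3 times the
  model's free-running period) and amplitudes (0 up to a model-scaled
  maximum: 0.1 for the clock model, 0.5 for the planar models, chosen
  so the deterministic tongue closes inside the scanned rectangle),
  default 21 x 21 cells, 10 transient + 20 measured cycles per cell.
  The grid-average PC summarizes a tongue in one number.  Every cell
  seeds its own RNG stream from (master seed, cell indices), so any
  cell can be recomputed in isolation, bit for bit, independent of
  scan order.
* **Noise sweep**: grid-average PC (and PPC) per (population size n,
  noise intensity sigma), with a second-order polynomial summary of
  the sigma dependence per n (`fit_noise_optimum`).
* **Fixed-volume sweep**: a total budget of `V` molecules split into
  `n` cells of size `Omega = V/n` each (`sigma = (V/n)^(-1/2)`); the
  integrator switches to the SSA automatically for small cells.
* **Heterogeneity sweep**: deterministic members with per-member
  thresholds `A_i ~ Normal(A0, sigma_A)` truncated to positive values
  (non-positive draws re-sampled and counted); models cell-to-cell
  variability instead of intrinsic noise.
* **PRC / jet lag**: defaults of 10 replicates with mean and sd
  reporting; jet-lag shift defaults to half the input period (the
  worst case); population sizes are configurable and are run at
  n = 50-100 in the test suite.

The published-scale population of n = 1000 oscillators on a 21 x 21
grid is outside routine test scale; the suite runs the population case
at n = 100 on a 9 x 9 or 11 x 11 grid, where the ordering
(population > deterministic > single stochastic cell) is already
unambiguous.  Sweep tests use 7 x 7 grids with 15 measured cycles.
Van der Pol comparisons use 5 x 5 grids at n = 100 with 5 + 10 cycles
per cell and sigma in {0, 0.1, 0.2}, matching the noise scale at which
the stochastic Van der Pol traces are illustrated.

## What the simulations do and do not emulate

The generator produces idealized study conditions: statistically
identical (or parametrically heterogeneous) oscillators, perfectly
shared square-wave input, no coupling, no measurement noise, and
stationary parameters.  Real population recordings (e.g. bioluminescence
assays) add reporter dynamics, detection noise, slow drifts and possible
weak coupling; passing tests here show the mathematical mechanism --
noise plus averaging widens entrainment -- not that any particular
biological tissue realizes it.  Heterogeneous-parameter populations can
contain members past a bifurcation with qualitatively different
dynamics; the heterogeneity sweep reports only average PC and makes no
claim about those members' waveforms.

## Numerical choices and edge cases

* Ties between equal peak candidates resolve to the earlier time
  (argmax); ties at a phase difference of exactly pi wrap to +pi.
* A constant signal yields an empty peak series, not an error; PC
  treats empty cycles as entrainment failures, PPC skips them.
* Deterministic homogeneous populations are simulated once and
  broadcast (members are identical by construction).
* `fit_noise_optimum` reports a vertex only when the fitted parabola
  opens downward.
* Config files are flat YAML/JSON mappings; unknown keys are rejected
  with the offending name, and `sigma` inconsistent with a given
  `omega_size` is an error rather than a silent preference.

## Known limitations

* Euler-Maruyama at dt = 0.001 carries an O(dt) period bias (~0.7% for
  the clock model); all comparisons are made within the same
  discretization, and the adaptive-solver cross-check uses a finer
  step.
* The SSA path simulates members sequentially; very large populations
  at small Omega are slow.
* PRC phase shifts are measured ~10 periods after the pulse; for very
  noisy populations phase diffusion between pulse and measurement
  inflates the replicate spread (reported in `sd_shift`).
* No coupled-oscillator or delay-equation variants; no parameter
  fitting to experimental recordings.
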