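"""Numba-compiled integration kernels.

The inner loops of the Euler-Maruyama and Gillespie integrators live
here so that population sweeps (hundreds of grid cells times hundreds of
oscillators) run at compiled speed.  Standard-normal increments are
pre-generated outside the kernels with NumPy's PCG64 streams (one stream
per population member) and consumed here; the event-driven SSA draws its
uniforms from numba's own generator, seeded per member.

Forcing enters the Euler-Maruyama kernels as a precomputed per-step
input array (left-endpoint evaluation); the SSA kernel receives the
input as breakpoint times plus piecewise-constant levels, and candidate
reaction times that overshoot the next forcing switch are rejected with
the clock advanced to the switch, which keeps the algorithm exact for
piecewise-constant propensities.

``FLOOR_DISABLED`` sentinels an inactive state floor.
"""

import numpy as np
from numba import njit

from .models import KF_TIME_SCALE

FLOOR_DISABLED = -1.0e300

# compile-time constant inside the jitted kernels
_TAU = KF_TIME_SCALE


@njit(cache=True)
def kf_em_chunk(state0, A_arr, sigma, dt, I_arr, noise,
                record_members, out_mean, out_members, floor):
    """Euler-Maruyama for a chunk of Kim-Forger oscillators.

    ``noise`` has shape (n_chunk, steps-1, 3): one pre-generated
    standard-normal increment per member, step and state variable.  The
    seven reaction channels partition over the three variables (X: 1-3,
    Y: 4-5, Z: 6-7) with one independent Wiener increment each, so their
    joint effect per step is exactly one normal increment per variable
    with variance sigma^2 * tau * (sum of the channel propensities):
    sqrt(f + X + I), sqrt(X + Y) and sqrt(Y + Z) respectively.
    ``A_arr`` holds one repression threshold per member.  Member X
    outputs are accumulated into ``out_mean`` (and written to
    ``out_members`` rows when recording).  Returns (clamp_counts,
    floored) per member; a floored member aborts at the violation.
    """
    n = noise.shape[0]
    steps = I_arr.shape[0]
    sqdt = np.sqrt(dt)
    st = sigma * np.sqrt(_TAU) * sqdt
    clamps = np.zeros(n, np.int64)
    floored = np.zeros(n, np.uint8)
    for i in range(n):
        x = state0[0]
        y = state0[1]
        z = state0[2]
        A = A_arr[i]
        for k in range(steps):
            out_mean[k] += x
            if record_members:
                out_members[i, k] = x
            if k == steps - 1:
                break
            I = I_arr[k]
            f = 1.0 - z / A
            if f < 0.0:
                f = 0.0
            dx = f - x + I
            dy = x - y
            dz = y - z
            if sigma > 0.0:
                xc = x
                yc = y
                zc = z
                if xc < 0.0:
                    xc = 0.0
                    clamps[i] += 1
                if yc < 0.0:
                    yc = 0.0
                    clamps[i] += 1
                if zc < 0.0:
                    zc = 0.0
                    clamps[i] += 1
                x += _TAU * dx * dt + st * np.sqrt(f + xc + I) * noise[i, k, 0]
                y += _TAU * dy * dt + st * np.sqrt(xc + yc) * noise[i, k, 1]
                z += _TAU * dz * dt + st * np.sqrt(yc + zc) * noise[i, k, 2]
            else:
                x += _TAU * dx * dt
                y += _TAU * dy * dt
                z += _TAU * dz * dt
            if floor > FLOOR_DISABLED / 2 and (x < floor or y < floor or z < floor):
                floored[i] = 1
                break
    return clamps, floored


@njit(cache=True)
def kf_em_single(state0, A, sigma, dt, I_arr, noise, floor):
    """Single Kim-Forger trajectory recording all three variables.

    ``noise`` has shape (steps-1, 3) (may be empty when sigma = 0);
    see :func:`kf_em_chunk` for the channel-merging convention.
    """
    steps = I_arr.shape[0]
    sqdt = np.sqrt(dt)
    st = sigma * np.sqrt(_TAU) * sqdt
    out = np.zeros((steps, 3))
    clamps = 0
    floored = False
    x = state0[0]
    y = state0[1]
    z = state0[2]
    for k in range(steps):
        out[k, 0] = x
        out[k, 1] = y
        out[k, 2] = z
        if k == steps - 1:
            break
        I = I_arr[k]
        f = 1.0 - z / A
        if f < 0.0:
            f = 0.0
        dx = f - x + I
        dy = x - y
        dz = y - z
        if sigma > 0.0:
            xc = x
            yc = y
            zc = z
            if xc < 0.0:
                xc = 0.0
                clamps += 1
            if yc < 0.0:
                yc = 0.0
                clamps += 1
            if zc < 0.0:
                zc = 0.0
                clamps += 1
            x += _TAU * dx * dt + st * np.sqrt(f + xc + I) * noise[k, 0]
            y += _TAU * dy * dt + st * np.sqrt(xc + yc) * noise[k, 1]
            z += _TAU * dz * dt + st * np.sqrt(yc + zc) * noise[k, 2]
        else:
            x += _TAU * dx * dt
            y += _TAU * dy * dt
            z += _TAU * dz * dt
        if floor > FLOOR_DISABLED / 2 and (x < floor or y < floor or z < floor):
            floored = True
            break
    return out, clamps, floored


@njit(cache=True)
def planar_em_chunk(state0, model_id, p1, p2, p3, sigma, dt, I_arr, noise,
                    record_members, out_mean, out_members):
    """Euler-Maruyama for a chunk of planar oscillators; accumulates X.

    model_id 0: Van der Pol with (p1, p2) = (d, B);
    model_id 1: amplitude-phase with (p1, p2, p3) = (lam, amp, omega).
    Additive noise on both components; ``noise`` is (n_chunk, steps-1, 2).
    """
    n = noise.shape[0]
    steps = I_arr.shape[0]
    s = sigma * np.sqrt(dt)
    for i in range(n):
        x = state0[0]
        y = state0[1]
        for k in range(steps):
            out_mean[k] += x
            if record_members:
                out_members[i, k] = x
            if k == steps - 1:
                break
            I = I_arr[k]
            if model_id == 0:
                dx = y
                dy = -(p2 * x * x - p1) * y - x + I
            else:
                R = np.sqrt(x * x + y * y)
                dx = p1 * x * (p2 - R) - p3 * y + I
                dy = p1 * y * (p2 - R) + p3 * x
            if sigma > 0.0:
                x += dx * dt + s * noise[i, k, 0]
                y += dy * dt + s * noise[i, k, 1]
            else:
                x += dx * dt
                y += dy * dt


@njit(cache=True)
def planar_em_single(state0, model_id, p1, p2, p3, sigma, dt, I_arr, noise):
    """Single planar-oscillator trajectory recording both variables."""
    steps = I_arr.shape[0]
    s = sigma * np.sqrt(dt)
    out = np.zeros((steps, 2))
    x = state0[0]
    y = state0[1]
    for k in range(steps):
        out[k, 0] = x
        out[k, 1] = y
        if k == steps - 1:
            break
        I = I_arr[k]
        if model_id == 0:
            dx = y
            dy = -(p2 * x * x - p1) * y - x + I
        else:
            R = np.sqrt(x * x + y * y)
            dx = p1 * x * (p2 - R) - p3 * y + I
            dy = p1 * y * (p2 - R) + p3 * x
        if sigma > 0.0:
            x += dx * dt + s * noise[k, 0]
            y += dy * dt + s * noise[k, 1]
        else:
            x += dx * dt
            y += dy * dt
    return out


@njit(cache=True)
def kf_ssa_single(counts0, omega, A, bp_times, bp_levels, grid, seed):
    """Exact SSA for the 7-reaction Kim-Forger scheme, one trajectory.

    ``bp_times``/``bp_levels`` describe the piecewise-constant input
    (len(bp_times) == len(bp_levels) + 1, spanning [0, t_end]).  The
    state is sampled onto ``grid`` by last-observation-carried-forward
    in count units.  Returns (counts_on_grid, absorbed).
    """
    np.random.seed(seed)
    x = float(counts0[0])
    y = float(counts0[1])
    z = float(counts0[2])
    nseg = bp_levels.shape[0]
    G = grid.shape[0]
    out = np.zeros((G, 3))
    g = 0
    seg = 0
    t = 0.0
    absorbed = False
    while seg < nseg:
        I = bp_levels[seg]
        next_sw = bp_times[seg + 1]
        a1 = omega - z / A
        if a1 < 0.0:
            a1 = 0.0
        a3 = omega * I
        c1 = _TAU * a1
        c2 = c1 + _TAU * x
        c3 = c2 + _TAU * a3
        c4 = c3 + _TAU * x
        c5 = c4 + _TAU * y
        c6 = c5 + _TAU * y
        a0 = c6 + _TAU * z
        if a0 <= 0.0:
            if seg == nseg - 1:
                absorbed = True
                break
            while g < G and grid[g] < next_sw:
                out[g, 0] = x
                out[g, 1] = y
                out[g, 2] = z
                g += 1
            t = next_sw
            seg += 1
            continue
        tau = -np.log(np.random.random()) / a0
        if t + tau >= next_sw:
            while g < G and grid[g] < next_sw:
                out[g, 0] = x
                out[g, 1] = y
                out[g, 2] = z
                g += 1
            t = next_sw
            seg += 1
            continue
        tnew = t + tau
        while g < G and grid[g] < tnew:
            out[g, 0] = x
            out[g, 1] = y
            out[g, 2] = z
            g += 1
        t = tnew
        r = np.random.random() * a0
        if r < c1:
            x += 1.0
        elif r < c2:
            x -= 1.0
        elif r < c3:
            x += 1.0
        elif r < c4:
            y += 1.0
        elif r < c5:
            y -= 1.0
        elif r < c6:
            z += 1.0
        else:
            z -= 1.0
    while g < G:
        out[g, 0] = x
        out[g, 1] = y
        out[g, 2] = z
        g += 1
    return out, absorbed
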