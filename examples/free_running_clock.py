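"""Free-running minimal clock: simulate the deterministic oscillator and
measure its period.

The three-variable negative-feedback model (X -> Y -> Z --| X) is
time-scaled so that, without input or noise, X peaks once per unit time.
Half of that period (0.5) is the standard pulse length for the
phase-response experiments.
"""

from oscent import ForcingProgram, KimForgerParams, SimConfig, euler_maruyama
from oscent.metrics import free_running_period

params = KimForgerParams()  # A = 0.1, sigma = 0
dark = ForcingProgram(T=1.0, Imax=0.0)  # no input
traj = euler_maruyama(params, dark, SimConfig(t_end=50.0))

period = free_running_period(traj, transient=20.0, min_separation=0.5)
print(f"free-running period : {period:.4f} (expected ~1.0)")
print(f"half period         : {period / 2:.4f} (PRC pulse length)")
print(f"X range on the cycle: [{traj.output().min():.3f}, {traj.output().max():.3f}]")
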