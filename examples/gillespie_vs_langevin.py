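"""Exact discrete simulation vs the chemical Langevin approximation.

At system size Omega = 1000 molecules (noise sigma = Omega^-1/2 ~ 0.032)
the two descriptions of the same reaction network should agree in their
population means.  Below Omega = 1000 the Langevin approximation
degrades and the package switches to the exact Gillespie algorithm
automatically (method='auto').
"""

import numpy as np

from oscent import ForcingProgram, KimForgerParams, SimConfig, simulate_population
from oscent.simulate import select_method

forcing = ForcingProgram(T=1.0, Imax=0.05)
n = 100
ssa = simulate_population(KimForgerParams(omega_size=1000), forcing,
                          SimConfig(t_end=10.0, n=n, seed=2, method="ssa",
                                    record_members=True))
cle = simulate_population(KimForgerParams(sigma=1000 ** -0.5), forcing,
                          SimConfig(t_end=10.0, n=n, seed=2, method="cle",
                                    record_members=True))

probes = np.linspace(1.0, 9.5, 6)
idx = np.searchsorted(ssa.mean_trajectory.times, probes)
for t, i in zip(probes, idx):
    a = ssa.mean_trajectory.output()[i]
    b = cle.mean_trajectory.output()[i]
    se = np.hypot(ssa.member_outputs[:, i].std() / np.sqrt(n),
                  cle.member_outputs[:, i].std() / np.sqrt(n))
    print(f"t={t:4.1f}: SSA mean {a:.4f}  CLE mean {b:.4f}  |diff|/SE = {abs(a-b)/se:.2f}")

print("\nautomatic method selection:")
for omega in (40_000, 1000, 500):
    print(f"  Omega = {omega:>6}: {select_method(omega=omega)}")
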