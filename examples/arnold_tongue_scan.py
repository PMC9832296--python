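"""Arnold tongues: entrainment across input periods and amplitudes.

Phase coherence (PC) is 1 when the population-mean signal peaks at the
same phase of every input cycle and near 0 otherwise.  Scanning PC over
a (period, amplitude) grid draws the tongue-shaped entrainment region;
its grid-average is a single-number summary of how widely the system
entrains.  Noise plus a population widens the tongue: the stochastic
population's average PC beats both the deterministic model and the
single stochastic cell.
"""

import numpy as np

from oscent import KimForgerParams
from oscent.experiments import arnold_tongue, default_axes

axes = default_axes(KimForgerParams(), n_periods=9, n_amplitudes=9)

det = arnold_tongue(KimForgerParams(), axes=axes, n=1, sigma=0.0, seed=1)
single = arnold_tongue(KimForgerParams(), axes=axes, n=1, sigma=0.005, seed=1)
pop = arnold_tongue(KimForgerParams(), axes=axes, n=100, sigma=0.005, seed=1)

print("average PC over the 9 x 9 tongue grid:")
print(f"  deterministic (sigma = 0)          : {det.average_pc:.3f}")
print(f"  single stochastic cell (sigma=5e-3): {single.average_pc:.3f}")
print(f"  population n = 100  (sigma = 5e-3) : {pop.average_pc:.3f}")
print("expected ordering: population > deterministic > single cell")

row = det.pc[-1]  # highest input amplitude
print("\ndeterministic PC along the top row (Imax = 0.1):")
print("  T/T0:", np.round(axes.periods, 2).tolist())
print("  PC  :", np.round(row, 2).tolist())
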