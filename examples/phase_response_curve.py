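"""Phase response of a stochastic population to a single input pulse.

A pulse of amplitude I and length 0.5 (half a free-running period) is
applied at several cyclic times to a free-running population; the phase
shift is measured against an unperturbed reference simulated with
identical noise.  At low I and low noise the shifts are small (type-1
response); raising the noise intensity alone drives the response toward
large, type-0 shifts approaching half a cycle.
"""

import numpy as np

from oscent import KimForgerParams
from oscent.experiments import prc_experiment

for sigma in (0.005, 0.05):
    tab = prc_experiment(KimForgerParams(sigma=sigma), I=0.01, n=50,
                         n_phases=6, replicates=5, seed=3)
    print(f"sigma = {sigma}:")
    for ph, m, s in zip(tab.pulse_phases, tab.mean_shift, tab.sd_shift):
        print(f"  pulse at phase {ph:.2f}: shift {m:+.3f} +/- {s:.3f} cycles")
    print(f"  PRC amplitude = {tab.amplitude:.3f} cycles "
          f"({'type 0' if tab.amplitude > 0.25 else 'type 1'})\n")
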