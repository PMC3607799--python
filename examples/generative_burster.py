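"""The one-variable generative parabolic burster.

dtheta/dt = I - cos(theta) - cos(theta/n) on a circle of circumference
2 pi n produces exactly n spikes per burst; the firing threshold is I = 2
for every n (SNIC), where the burst-cycle period diverges.
"""

import numpy as np

from burstnet import (PhaseParams, SimSettings, firing_threshold, isi_profile,
                      period_single, simulate_phase_single, spikes_per_cycle)

for n in (1, 3, 5, 10):
    print(f"n = {n:2d}: firing threshold I_c = {firing_threshold(n):.6f}")

print("\nburst-cycle period T(I) for n = 5 (quadrature):")
for I in (2.5, 2.1, 2.01, 2.001):
    print(f"  I = {I:6.3f}: T = {period_single(I, 5):9.2f}")

traj = simulate_phase_single(PhaseParams(I=2.01, n=5),
                             SimSettings(t_end=600.0, t_transient=100.0))
isi = isi_profile(traj)
print(f"\nI = 2.01, n = 5: {spikes_per_cycle(traj)} spikes per burst cycle")
print("within-burst ISIs:", np.round(isi, 2),
      "(first and last exceed the interior: parabolic)")
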