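"""Fit Bell (slip-bond) force laws to rate-vs-force series.

Dissociation rates grow exponentially with clamp force, k(f) =
k0 exp(f/f_scale); transition rates vanish at zero force and follow
k_a (exp(f/f_scale) - 1).  Both laws are fitted here to noisy synthetic
series and read back as parameters with physical units.
"""

import numpy as np

from bondkin import bell_rate, fit_bell, fit_transition, transition_rate
from bondkin.params import BellParams

rng = np.random.default_rng(1)
forces = np.linspace(0.0, 17.5, 8)  # pN

# dissociation rate: Bell law with k0 = 0.35 s^-1, f_scale = 7 pN,
# corrupted by 10% multiplicative (log-normal) noise
true = BellParams(k0=0.35, f_scale=7.0)
rates = bell_rate(true, forces) * np.exp(rng.normal(0, 0.1, len(forces)))
b = fit_bell(forces, rates)
print(f"Bell fit: k0 = {b.k0:.3f} s^-1 (true 0.35), "
      f"f_scale = {b.f_scale:.2f} pN (true 7.0), slip bond: {b.is_slip}")
# f_scale is the force that multiplies the rate by e; a positive value
# means force accelerates dissociation (slip bond)

# transition rate: zero at zero force, activated exponentially
k_tr = transition_rate(0.55, 4.0, forces[1:])
k_tr_noisy = k_tr * np.exp(rng.normal(0, 0.05, len(k_tr)))
ka, fs = fit_transition(forces[1:], k_tr_noisy)
print(f"activated-law fit: k_a = {ka:.3f} s^-1 (true 0.55), "
      f"f_scale = {fs:.2f} pN (true 4.0)")
print(f"transition rate at f = 0: {transition_rate(ka, fs, 0.0)} s^-1")
# exactly zero: conformational transitions require force
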