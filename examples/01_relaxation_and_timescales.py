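"""Evaluate the relaxation modulus of a monolayer-scale material.

Builds the four-parameter fractional model (spring-pot + dashpot in series,
spring in parallel), prints G(t) across the power-law, cut-off and plateau
regimes, and the derived characteristic times.
"""

import numpy as np

from rheofract import FractionalModelParams, characteristic_times, relaxation_modulus

params = FractionalModelParams(c_beta=200.0, beta=0.3, eta=1000.0, k=100.0)
ts = characteristic_times(params)

print(f"material: c_beta={params.c_beta} Pa s^beta, beta={params.beta}, "
      f"eta={params.eta} Pa s, k={params.k} Pa")
print(f"tau1 = {ts.tau1:.2f} s   (dashpot takes over from the spring-pot)")
print(f"tau2 = {ts.tau2:.2f} s   (spring retardation time eta/k)")
print(f"xi   = {ts.xi:.2f}       -> creep regime: {ts.regime}")
print()
print("   t (s)    G(t) (Pa)")
for t in (0.01, 0.1, 1.0, 10.0, 60.0, 600.0):
    print(f"{t:8.2f}  {relaxation_modulus(params, t):10.1f}")
print()
print("Short times follow the power law c_beta t^-beta / Gamma(1-beta) + k;")
print("beyond tau1 the modulus drops quickly to the plateau k "
      f"= {params.k:.0f} Pa (the parallel spring).")
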