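"""Incomplete recovery under on/off force cycles: four model variants.

Simulates the bead micro-rheology protocol — constant force on, force off,
repeated — for (b) a lone spring-pot, (c) spring-pot + dashpot, (d) the full
model, and (e) the full model with the spring reduced to 10 %.  Output is
normalized to the first peak, the only comparable quantity when the probe
geometry is unknown.
"""

import numpy as np

from rheofract import FractionalModelParams, cyclic_force_response

beta, c, eta, k_full = 0.3, 200.0, 1000.0, 200.0
variants = {
    "spring-pot only": FractionalModelParams.spring_pot(c, beta),
    "spring-pot + dashpot": FractionalModelParams.fractional_maxwell(c, beta, eta),
    "full model": FractionalModelParams(c, beta, eta, k_full),
    "full model, k/10": FractionalModelParams(c, beta, eta, 0.1 * k_full),
}

n_cycles = 6
print(f"residual displacement at the end of each off-phase "
      f"({n_cycles} cycles, first-peak units):")
header = "  ".join(f"cyc{i+1}" for i in range(n_cycles - 1))
print(f"{'variant':22s}  {header}")
for name, p in variants.items():
    ser = cyclic_force_response(p, 100.0, 5.0, 5.0, n_cycles)
    ends = [ser.strain[np.searchsorted(ser.time, 10.0 * (i + 1))]
            for i in range(n_cycles - 1)]
    print(f"{name:22s}  " + "  ".join(f"{e:4.2f}" for e in ends))

print()
print("The spring-pot alone recovers almost completely (first-cycle residual")
print(f"2^beta - 1 = {2**beta - 1:.3f}); the dashpot adds an unbounded linear")
print("drift; the full spring halts it; a 10x weaker spring sits in between.")
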