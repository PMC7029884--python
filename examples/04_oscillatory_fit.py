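"""Fit storage and loss moduli from an oscillatory sweep.

Generates a noisy G'/G'' sweep over four decades of frequency (2 %
multiplicative noise, as in AFM-style dynamic measurements) and fits the
model jointly to both moduli with relative residuals.
"""

import numpy as np

from rheofract import (
    FractionalModelParams,
    NoiseSpec,
    complex_modulus,
    fit_oscillatory,
    generate_oscillatory,
)

truth = FractionalModelParams(c_beta=200.0, beta=0.3, eta=1000.0, k=100.0)
omega = np.logspace(-2, 2, 30)
_, gp, gpp = generate_oscillatory(truth, omega, NoiseSpec(0.02, seed=7))

fit = fit_oscillatory(omega, gp, gpp, n_starts=5, seed=7)
p = fit.params
print("recovered parameters (truth 200, 0.3, 1000, 100):")
print(f"  c_beta = {p.c_beta:8.2f} Pa s^b    beta = {p.beta:.4f}")
print(f"  eta    = {p.eta:8.1f} Pa s       k    = {p.k:.2f} Pa")

w_show = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
mp, mpp = complex_modulus(p, w_show)
print()
print(" omega (rad/s)   G' (Pa)   G'' (Pa)")
for w, a, b in zip(w_show, mp, mpp):
    print(f"{w:13.2f} {a:9.1f} {b:10.1f}")
print()
print("G' plateaus at k at low frequency; both moduli follow the spring-pot")
print("power law omega^beta with loss angle beta*pi/2 at high frequency.")
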