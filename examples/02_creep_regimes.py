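"""The three creep morphologies selected by xi = tau1/tau2.

Computes J(t) by numerical Laplace inversion for three spring stiffnesses
and reports the largest local log-log slope: xi << 1 lets the dashpot flow
freely (slope toward 1) before the spring saturates; xi > 1 suppresses the
viscous excursion entirely.  Every k > 0 material ends in a plateau J = 1/k.
"""

import numpy as np

from rheofract import FractionalModelParams, creep_compliance

beta, c, eta = 0.3, 200.0, 1000.0
tau1 = (eta / c) ** (1.0 / (1.0 - beta))

print("     xi    k (Pa)   max d(ln J)/d(ln t)   final slope")
for xi in (0.001, 0.1, 1.0, 10.0):
    k = eta * xi / tau1
    p = FractionalModelParams(c_beta=c, beta=beta, eta=eta, k=k)
    t = np.logspace(-3, 5, 300) * max(tau1, eta / k)
    j = creep_compliance(p, t)
    slopes = np.diff(np.log(j)) / np.diff(np.log(t))
    print(f"{xi:7.3f}  {k:8.1f}   {slopes.max():19.3f}   {slopes[-1]:11.2e}")

print()
print("Slope ~beta at short times (spring-pot), rising toward 1 only when")
print("xi is small (dissipative-first), and collapsing to 0 at the plateau.")
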