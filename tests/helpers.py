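"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths of the package: the Mittag-Leffler
oracle is a plain arbitrary-precision truncated series (plus the spectral
integral representation for deep-negative arguments, where the series
would need thousands of digits), and the hereditary-integral oracle is an
adaptive-quadrature Boltzmann convolution.
"""

from __future__ import annotations

import math

import mpmath
import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as _gamma

_SERIES_U_CAP = 120.0  # beyond this scale the series oracle gets too slow


def ml_series_oracle(z: float, a: float, b: float) -> float:
    """Truncated power series at adaptive precision (cancellation-aware)."""
    u = abs(z) ** (1.0 / a)
    dps = int(40 + 1.4 * u / math.log(10.0))
    with mpmath.workdps(dps):
        am, bm, zm = mpmath.mpf(a), mpmath.mpf(b), mpmath.mpf(z)
        acc, zp = mpmath.mpf(0), mpmath.mpf(1)
        for n in range(500000):
            term = zp / mpmath.gamma(am * n + bm)
            acc += term
            zp *= zm
            if a * n + b > u and abs(term) < mpmath.mpf(10) ** (-35) * (
                abs(acc) + mpmath.mpf(10) ** (-50)
            ):
                break
        return float(acc)


def _ml_spectral_oracle(z: float, a: float, b: float) -> float:
    """Spectral integral for z < 0, 0 < a < 1; b reduced into (0, 1] by the
    Mittag-Leffler recurrences (valid here since |z| > 1)."""
    if b > 1.0:
        return (_ml_spectral_oracle(z, a, b - a) - 1.0 / _gamma(b - a)) / z
    if b <= 0.0:
        return z * _ml_spectral_oracle(z, a, b + a) + 1.0 / _gamma(b)
    x = -z
    s1 = math.sin(math.pi * (1.0 - b))
    s2 = math.sin(math.pi * (1.0 - b + a))
    cc = math.cos(math.pi * a)

    def kernel(r):
        num = r * s1 + x * s2
        den = r * r + 2.0 * r * x * cc + x * x
        return r ** ((1.0 - b) / a) * math.exp(-(r ** (1.0 / a))) * num / den

    v1, _ = quad(kernel, 0.0, x, epsabs=0.0, epsrel=1e-12, limit=500)
    v2, _ = quad(kernel, x, np.inf, epsabs=0.0, epsrel=1e-12, limit=500)
    return (v1 + v2) / (math.pi * a)


def ml_oracle(z: float, a: float, b: float) -> float:
    """Reference Mittag-Leffler value for real z."""
    if z >= 0.0 or a >= 1.0 or abs(z) ** (1.0 / a) <= _SERIES_U_CAP:
        return ml_series_oracle(z, a, b)
    return _ml_spectral_oracle(z, a, b)


def boltzmann_stress_oracle(params, protocol, t: float) -> float:
    """Adaptive-quadrature Boltzmann convolution for a strain protocol.

    ``sigma(t) = k eps(t) + sum_seg rate int G_branch(t - u) du`` with the
    weak ``(t-u)^-beta`` singularity removed by the substitution
    ``w = (t - u)^(1-beta)``.
    """
    from rheofract.mittag_leffler import mittag_leffler

    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    total = k * float(protocol.value(t))
    for t0, t1, rate in protocol.segments():
        hi = min(t, t1)
        if hi <= t0:
            continue
        if beta == 0.0:
            if math.isinf(eta):
                f = lambda u: c
            else:
                f = lambda u: c * math.exp(-(c / eta) * (t - u))
            v, _ = quad(f, t0, hi, epsabs=1e-14, epsrel=1e-11, limit=300)
        else:
            a = 1.0 - beta
            lam = 0.0 if math.isinf(eta) else c / eta
            w1, w2 = (t - hi) ** a, (t - t0) ** a
            g = lambda w: (c / a) * float(mittag_leffler(-lam * w, a, a))
            v, _ = quad(g, w1, w2, epsabs=1e-14, epsrel=1e-11, limit=300)
        total += rate * v
    return total


def sls_closed_forms(c: float, eta: float, k: float):
    """Textbook standard-linear-solid response functions (beta = 0 oracle)."""
    tau = eta / c

    def G(t):
        return c * np.exp(-np.asarray(t) / tau) + k

    def J(t):
        t = np.asarray(t)
        if k == 0.0:
            return 1.0 / c + t / eta
        tau_r = eta * (k + c) / (c * k)
        return 1.0 / k - (1.0 / k - 1.0 / (k + c)) * np.exp(-t / tau_r)

    def G_star(w):
        w = np.asarray(w)
        den = 1.0 + (w * tau) ** 2
        return k + c * (w * tau) ** 2 / den, c * w * tau / den

    def ramp_stress(rate, t):
        # constant-rate ramp: k eps + eta rate (1 - exp(-t/tau))
        t = np.asarray(t)
        return k * rate * t + eta * rate * (1.0 - np.exp(-t / tau))

    return G, J, G_star, ramp_stress
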