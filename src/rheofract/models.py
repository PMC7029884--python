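"""The generalized fractional viscoelastic model and its response functions.

The model is a fractional Maxwell branch — a spring-pot (stress proportional
to the ``beta``-th fractional derivative of strain, constant ``c_beta``) in
series with a dashpot ``eta`` — in parallel with a spring ``k``.  It captures
the biphasic mechanics typical of cells and cellularised tissues: a
short-time power law ``t^-beta``, an exponential cut-off around the time
``tau1 = (eta/c_beta)^(1/(1-beta))`` at which the dashpot takes over, and a
long-time stress plateau set by ``k``.

Degenerate limits are first-class citizens:

* ``beta = 0``   — standard linear solid (SLS), all responses closed-form;
* ``k = 0``      — fractional Maxwell model (FMM), a fluid with no plateau;
* ``eta = inf``  — spring-pot (+ spring: fractional Kelvin–Voigt), the pure
                   power-law materials reported for single cells.

This module evaluates the relaxation modulus ``G(t)``, creep compliance
``J(t)`` (numerical Laplace inversion where no closed form exists), complex
modulus ``G* = G' + iG''``, the characteristic times ``tau1``, ``tau2 =
eta/k``, ``tau2' = (c_beta/k)^(1/beta)`` with the creep-regime ratio
``xi = tau1/tau2``, the relaxation spectrum ``H(tau)``, and the
master-curve normalization that collapses relaxation records sharing one
``beta``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gamma as _gamma

from .laplace import invert
from .mittag_leffler import mittag_leffler

__all__ = [
    "FractionalModelParams",
    "DerivedTimescales",
    "BETA_MAX",
    "REGIME_TOLERANCE",
    "relaxation_modulus",
    "laplace_relaxation",
    "laplace_creep",
    "creep_compliance",
    "complex_modulus",
    "characteristic_times",
    "relaxation_spectrum",
    "master_curve_transform",
    "SpectrumError",
]

# beta = 1 makes the spring-pot a plain dashpot and the relaxation kernel
# E_{0,0} ill-defined; the admissible range is capped just below 1.
BETA_MAX = 1.0 - 1e-6

# half-width of the "simultaneous" creep-regime band around xi = 1
REGIME_TOLERANCE = 0.25


class SpectrumError(ValueError):
    """Continuation for the relaxation spectrum hit a singularity."""


@dataclass(frozen=True)
class FractionalModelParams:
    """Material constants of the generalized fractional model.

    Parameters
    ----------
    c_beta : float
        Spring-pot firmness, Pa s^beta; > 0.
    beta : float
        Spring-pot exponent in [0, 1): 0 is a spring, values toward 1
        approach a dashpot.
    eta : float
        Dashpot viscosity, Pa s; > 0, ``inf`` removes the dashpot.
    k : float
        Parallel spring stiffness, Pa; >= 0, 0 removes the spring.
    """

    c_beta: float
    beta: float
    eta: float = math.inf
    k: float = 0.0

    def __post_init__(self) -> None:
        if not (self.c_beta > 0 and math.isfinite(self.c_beta)):
            raise ValueError(f"c_beta must be positive and finite, got {self.c_beta}")
        if not (0.0 <= self.beta <= BETA_MAX):
            raise ValueError(f"beta must lie in [0, {BETA_MAX}], got {self.beta}")
        if not self.eta > 0:
            raise ValueError(f"eta must be positive (inf allowed), got {self.eta}")
        if not (self.k >= 0 and math.isfinite(self.k)):
            raise ValueError(f"k must be non-negative and finite, got {self.k}")

    # -- sub-model constructors ------------------------------------------
    @classmethod
    def spring_pot(cls, c_beta: float, beta: float) -> "FractionalModelParams":
        """Lone spring-pot: pure power-law material."""
        return cls(c_beta=c_beta, beta=beta, eta=math.inf, k=0.0)

    @classmethod
    def fractional_maxwell(
        cls, c_beta: float, beta: float, eta: float
    ) -> "FractionalModelParams":
        """Spring-pot + dashpot in series (FMM): fluid, no plateau."""
        return cls(c_beta=c_beta, beta=beta, eta=eta, k=0.0)

    @classmethod
    def standard_linear_solid(
        cls, c: float, eta: float, k: float
    ) -> "FractionalModelParams":
        """beta = 0 degeneration: Maxwell arm (spring c + dashpot) || spring k."""
        return cls(c_beta=c, beta=0.0, eta=eta, k=k)

    @classmethod
    def fractional_kelvin_voigt(
        cls, c_beta: float, beta: float, k: float
    ) -> "FractionalModelParams":
        """Spring-pot in parallel with a spring (no dashpot)."""
        return cls(c_beta=c_beta, beta=beta, eta=math.inf, k=k)

    # -- derived ----------------------------------------------------------
    @property
    def tau1(self) -> float:
        """Spring-pot-to-dashpot crossover time (inf without a dashpot)."""
        if math.isinf(self.eta):
            return math.inf
        return (self.eta / self.c_beta) ** (1.0 / (1.0 - self.beta))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "c_beta": self.c_beta,
            "beta": self.beta,
            "eta": None if math.isinf(self.eta) else self.eta,
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FractionalModelParams":
        eta = d.get("eta", None)
        return cls(
            c_beta=float(d["c_beta"]),
            beta=float(d["beta"]),
            eta=math.inf if eta is None else float(eta),
            k=float(d.get("k", 0.0)),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "FractionalModelParams":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class DerivedTimescales:
    """Characteristic times of the model; ``None`` marks an undefined field.

    ``tau1`` — dashpot onset (relaxation cut-off); ``tau2 = eta/k`` — spring
    retardation time in creep; ``tau2_prime = (c_beta/k)^(1/beta)`` — the
    fractional Kelvin–Voigt time controlling creep when the spring saturates
    first; ``xi = tau1/tau2`` selects among the three creep morphologies.
    """

    tau1: float
    tau2: Optional[float]
    tau2_prime: Optional[float]
    xi: Optional[float]
    regime: Optional[str]


def relaxation_modulus(params: FractionalModelParams, t) -> np.ndarray:
    """Stress relaxation modulus ``G(t)`` (Pa) for ``t > 0``.

    ``G(t) = c_beta t^-beta E_{1-beta,1-beta}(-(t/tau1)^(1-beta)) + k``;
    the Mittag-Leffler factor interpolates between the short-time power law
    ``c_beta t^-beta / Gamma(1-beta)`` and the exponential-like cut-off
    beyond ``tau1``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("relaxation modulus requires t > 0 (diverges at 0)")
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    if beta == 0.0:
        if math.isinf(eta):
            return np.full(t.shape, c + k)
        return c * np.exp(-(c / eta) * t) + k
    a = 1.0 - beta
    if math.isinf(eta):
        return c * t ** (-beta) / _gamma(a) + k
    lam = c / eta
    return c * t ** (-beta) * mittag_leffler(-lam * t**a, a, a) + k


def laplace_relaxation(params: FractionalModelParams, s) -> np.ndarray:
    """Laplace transform ``G~(s)`` of the relaxation modulus (Pa s).

    ``G~(s) = k/s + eta / (1 + (tau1 s)^(1-beta))``; complex ``s`` off the
    negative real axis is accepted (needed by the Talbot contour and the
    spectrum continuation).
    """
    s = np.asarray(s)
    if s.dtype.kind in "fiu" and np.any(s <= 0.0):
        raise ValueError("laplace_relaxation requires s > 0 on the real line")
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    if math.isinf(eta):
        return k / s + c * s ** (beta - 1.0)
    # eta / (1 + (tau1 s)^(1-beta)) with (tau1 s)^(1-beta) = (eta/c) s^(1-beta)
    return k / s + eta / (1.0 + (eta / c) * s ** (1.0 - beta))


def laplace_creep(params: FractionalModelParams, s) -> np.ndarray:
    """Laplace transform ``J~(s)`` of the creep compliance (1/(Pa s)).

    Defined through the linear-viscoelastic reciprocity
    ``G~(s) J~(s) = s^-2``; for ``k > 0`` this is
    ``J~ = (1/(k s)) [1 + (tau1 s)^(1-beta)] /
    [(eta/k) s + 1 + (tau1 s)^(1-beta)]`` and the ``k = 0`` limit is
    ``J~ = [1 + (tau1 s)^(1-beta)] / (eta s^2)``.
    """
    s = np.asarray(s)
    if s.dtype.kind in "fiu" and np.any(s <= 0.0):
        raise ValueError("laplace_creep requires s > 0 on the real line")
    return 1.0 / (s * s * laplace_relaxation(params, s))


# below this fraction of tau1 (and of the spring-pot/spring crossover) the
# short-time spring-pot series replaces the numerical inversion of J~
_CREEP_SHORT_TIME = 1e-8


def creep_compliance(
    params: FractionalModelParams, t, tol: float = 1e-7
) -> np.ndarray:
    """Creep compliance ``J(t)`` (1/Pa) for ``t >= 0``.

    Closed forms are used for every degenerate branch (SLS, FMM fluid,
    spring-pot, fractional Kelvin–Voigt); the full model is inverted
    numerically from ``J~(s)`` on the Talbot contour, switching to the
    short-time spring-pot series ``t^beta/(c_beta Gamma(1+beta))`` below
    ``1e-8 tau1`` where the inversion would lose relative accuracy.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("creep compliance requires t >= 0")
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    out = np.empty(t.shape, dtype=float)
    zero = t == 0.0
    out[zero] = 0.0 if beta > 0.0 else 1.0 / (c + k)
    pos = ~zero
    tp = t[pos]
    if beta == 0.0:
        if math.isinf(eta):
            out[pos] = 1.0 / (c + k)
        elif k == 0.0:  # Maxwell fluid
            out[pos] = 1.0 / c + tp / eta
        else:  # SLS: retardation time eta (k + c) / (c k)
            tau_r = eta * (k + c) / (c * k)
            out[pos] = 1.0 / k - (1.0 / k - 1.0 / (k + c)) * np.exp(-tp / tau_r)
        return out
    if math.isinf(eta):
        if k == 0.0:
            out[pos] = tp**beta / (c * _gamma(1.0 + beta))
        else:  # fractional Kelvin-Voigt
            z = -(k / c) * tp**beta
            out[pos] = tp**beta / c * mittag_leffler(z, beta, 1.0 + beta)
        return out
    if k == 0.0:  # FMM fluid: spring-pot and dashpot compliances add
        out[pos] = tp / eta + tp**beta / (c * _gamma(1.0 + beta))
        return out
    # full model: numerical inversion
    tau1 = params.tau1
    t_short = _CREEP_SHORT_TIME * tau1
    short = pos & (t <= t_short)
    out[short] = t[short] ** beta / (c * _gamma(1.0 + beta))
    rest = pos & (t > t_short)
    if np.any(rest):
        out[rest] = invert(lambda s: laplace_creep(params, s), t[rest], tol=tol)
    return out


def complex_modulus(params: FractionalModelParams, omega):
    """Storage and loss moduli ``(G', G'')`` (Pa) at angular frequency omega.

    Derived from the network topology: the FMM branch combines the
    spring-pot impedance ``c_beta (i omega)^beta`` and the dashpot impedance
    ``i omega eta`` in series, and the spring adds in parallel::

        G*(omega) = k + [i omega eta * c_beta (i omega)^beta]
                        / [i omega eta + c_beta (i omega)^beta]

    At low frequency ``G' -> k``; at high frequency both moduli follow the
    spring-pot power law ``~ omega^beta`` with loss angle ``beta pi / 2``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0.0):
        raise ValueError("complex modulus requires omega > 0")
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    iw = 1j * omega
    zp = c * iw**beta
    if math.isinf(eta):
        g = k + zp
    else:
        g = k + (iw * eta * zp) / (iw * eta + zp)
    return np.real(g), np.imag(g)


def characteristic_times(
    params: FractionalModelParams, regime_tol: float = REGIME_TOLERANCE
) -> DerivedTimescales:
    """Characteristic times, dimensionless ratio xi and creep-regime label.

    Regimes (xi = tau1/tau2): ``dissipative-first`` (xi < 1: spring-pot ->
    dashpot -> spring plateau), ``spring-first`` (xi > 1: the spring
    saturates before the dashpot engages; fractional Kelvin–Voigt behaviour
    with time ``tau2'``), ``simultaneous`` for xi within the tolerance band
    ``[1 - regime_tol, 1/(1 - regime_tol)]``.  Undefined quantities
    (``tau2``, ``xi`` for k = 0; ``tau2'`` for beta = 0; the ratio when the
    dashpot is absent) are reported as ``None``, not zero.
    """
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    tau1 = params.tau1
    tau2 = (eta / k) if k > 0 else None
    tau2_prime = (c / k) ** (1.0 / beta) if (k > 0 and beta > 0) else None
    xi = None
    if k > 0 and math.isfinite(eta):
        xi = tau1 / tau2
    regime = None
    if xi is not None:
        lo, hi = 1.0 - regime_tol, 1.0 / (1.0 - regime_tol)
        if xi < lo:
            regime = "dissipative-first"
        elif xi > hi:
            regime = "spring-first"
        else:
            regime = "simultaneous"
    return DerivedTimescales(
        tau1=tau1, tau2=tau2, tau2_prime=tau2_prime, xi=xi, regime=regime
    )


def relaxation_spectrum(
    params: FractionalModelParams, tau_grid, angle_offset: float = 1e-3
) -> np.ndarray:
    """Relaxation spectrum ``H(tau)`` (Pa per unit ln tau).

    Computed from the analytic continuation of the dynamic modulus onto the
    upper lip of the negative real axis::

        H(tau) = (1/pi) Im[ s G~(s) ]  at  s = (1/tau) e^{i (pi - eps)}

    with ``eps = angle_offset``.  For ``beta > 0`` the continuation is
    smooth there (the FMM branch pole sits off the principal sheet); for
    ``beta = 0`` the discrete Maxwell time appears as a Lorentzian of width
    ``eps``.  For the spring-pot, ``H(tau) = (c_beta/pi) sin(beta pi)
    tau^-beta`` is recovered; for the full model the spectrum decays beyond
    the cut-off ``tau1``.
    """
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau <= 0.0):
        raise ValueError("relaxation spectrum requires tau > 0")
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    s = (1.0 / tau) * np.exp(1j * (np.pi - angle_offset))
    if math.isinf(eta):
        g_dyn = k + c * s**beta
    else:
        denom = 1.0 + (eta / c) * s ** (1.0 - beta)
        if np.any(np.abs(denom) < 1e-12):
            raise SpectrumError(
                "continuation hit the branch-cut singularity; "
                "increase angle_offset"
            )
        g_dyn = k + eta * s / denom
    return np.imag(g_dyn) / np.pi


def master_curve_transform(curve, params: FractionalModelParams):
    """Collapse a relaxation record onto the model's master curve.

    Returns ``(t/tau1, (G - k) tau1^beta / c_beta)``.  Substituting the
    relaxation modulus shows the transformed curve depends on ``t/tau1``
    and ``beta`` only, so records sharing ``beta`` — e.g. treated and
    untreated monolayers — collapse onto one branch regardless of
    ``c_beta``, ``eta`` and ``k``.

    ``curve`` is either a pair of arrays ``(t, G)`` or an object with
    ``time``/``stress``/``strain`` attributes (the modulus is then
    ``stress / max |strain|``).
    """
    if hasattr(curve, "time"):
        t = np.asarray(curve.time, dtype=float)
        eps0 = float(np.max(np.abs(np.asarray(curve.strain, dtype=float))))
        g = np.asarray(curve.stress, dtype=float) / eps0
    else:
        t, g = (np.asarray(x, dtype=float) for x in curve)
    if np.any(t <= 0.0):
        raise ValueError("master-curve transform requires strictly positive times")
    tau1 = params.tau1
    if not math.isfinite(tau1):
        raise ValueError("master-curve transform needs a finite tau1 (dashpot)")
    scale = tau1**params.beta / params.c_beta
    return t / tau1, (g - params.k) * scale
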