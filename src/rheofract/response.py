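"""Time-domain responses to arbitrary piecewise-linear loading protocols.

Linear viscoelasticity makes the response to any loading history a
Boltzmann superposition: increments of strain convolve with the relaxation
modulus ``G``, increments of stress with the creep compliance ``J``.  For a
piecewise-linear controlled variable each segment contributes a constant
rate, so the hereditary integral reduces to differences of the *running
integrals* of ``G`` or ``J``.  For the fractional model the strain-side
integral has a closed form through the Mittag-Leffler antiderivative::

    int_0^t u^-beta E_{1-beta,1-beta}(-lam u^(1-beta)) du
        = t^(1-beta) E_{1-beta,2-beta}(-lam t^(1-beta))

so ramp–hold (relaxation), slow stretch and cyclic experiments are evaluated
without numerical quadrature.  The stress-side integral ``int J`` is closed
form in every degenerate branch and is otherwise obtained by Talbot
inversion of ``J~(s)/s``.

Idealized steps are supported on the stress side (creep, cyclic
force protocols); on the strain side steps are realized as fast ramps at a
configurable rate, mirroring how the experiments actually load the sample
(default 75 %/s, with time zero at the start of the loading ramp).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gamma as _gamma

from .laplace import invert
from .mittag_leffler import mittag_leffler
from .models import FractionalModelParams, creep_compliance

__all__ = [
    "LoadingProtocol",
    "MechanicalTimeSeries",
    "DEFAULT_STEP_STRAIN_RATE",
    "stress_response",
    "strain_response",
    "cyclic_force_response",
]

# experimental loading-ramp rate used to realize "steps" in strain
DEFAULT_STEP_STRAIN_RATE = 0.75  # 1/s (75 % per second)


@dataclass(frozen=True)
class LoadingProtocol:
    """Piecewise-linear history of the controlled variable.

    ``controlled`` is ``"strain"`` (dimensionless) or ``"stress"`` (Pa).
    ``nodes`` are ``(time, value)`` pairs starting at ``(0, 0)`` with
    strictly increasing times; between nodes the history is linear and
    after the last node it holds constant.  On the stress side a node may
    repeat the previous time to encode an idealized step.
    """

    controlled: str
    nodes: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.controlled not in ("strain", "stress"):
            raise ValueError(f"controlled must be strain|stress, got {self.controlled}")
        nodes = tuple((float(t), float(v)) for t, v in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if not nodes or nodes[0] != (0.0, 0.0):
            raise ValueError("protocol must start at node (0, 0)")
        times = [t for t, _ in nodes]
        diffs = np.diff(times)
        if self.controlled == "strain":
            if np.any(diffs <= 0):
                raise ValueError("strain protocols need strictly increasing times")
        elif np.any(diffs < 0):
            raise ValueError("node times must be non-decreasing")

    # -- constructors -----------------------------------------------------
    @classmethod
    def ramp_hold(
        cls,
        amplitude: float,
        rate: float,
        hold: float,
        controlled: str = "strain",
    ) -> "LoadingProtocol":
        """Constant-rate ramp to ``amplitude``, then hold — the relaxation
        (or ramp-loaded creep) protocol."""
        if rate <= 0:
            raise ValueError("ramp rate must be positive")
        t_ramp = abs(amplitude) / rate
        return cls(
            controlled,
            ((0.0, 0.0), (t_ramp, amplitude), (t_ramp + hold, amplitude)),
        )

    @classmethod
    def step(cls, amplitude: float, controlled: str = "stress") -> "LoadingProtocol":
        """Idealized step at t = 0 (stress-controlled protocols only)."""
        return cls(controlled, ((0.0, 0.0), (0.0, amplitude)))

    @classmethod
    def constant_rate(
        cls, rate: float, duration: float, controlled: str = "strain"
    ) -> "LoadingProtocol":
        """Uninterrupted constant-rate loading (the slow-stretch protocol)."""
        return cls(controlled, ((0.0, 0.0), (duration, rate * duration)))

    @classmethod
    def cyclic(
        cls,
        amplitude: float,
        on_duration: float,
        off_duration: float,
        n_cycles: int,
        ramp_time: float = 0.0,
        controlled: str = "stress",
    ) -> "LoadingProtocol":
        """On/off rectangular cycles; ``ramp_time > 0`` replaces the
        idealized steps with fast ramps."""
        if n_cycles < 1:
            raise ValueError("need at least one cycle")
        if on_duration <= 0 or off_duration <= 0:
            raise ValueError("cycle durations must be positive")
        if ramp_time < 0 or 2 * ramp_time >= min(on_duration, off_duration):
            if ramp_time != 0.0:
                raise ValueError("ramp_time must fit inside each phase")
        nodes = [(0.0, 0.0)]
        t = 0.0
        for _ in range(n_cycles):
            nodes.append((t + ramp_time, amplitude))
            t += on_duration
            nodes.append((t, amplitude))
            nodes.append((t + ramp_time, 0.0))
            t += off_duration
            nodes.append((t, 0.0))
        # drop duplicate consecutive nodes created when ramp_time == 0
        cleaned = [nodes[0]]
        for nd in nodes[1:]:
            if nd != cleaned[-1]:
                cleaned.append(nd)
        return cls(controlled, tuple(cleaned))

    # -- evaluation -------------------------------------------------------
    @property
    def duration(self) -> float:
        return self.nodes[-1][0]

    def segments(self) -> List[Tuple[float, float, float]]:
        """Finite-rate pieces ``(t_start, t_end, rate)`` (steps excluded)."""
        out = []
        for (t0, v0), (t1, v1) in zip(self.nodes[:-1], self.nodes[1:]):
            if t1 > t0 and v1 != v0:
                out.append((t0, t1, (v1 - v0) / (t1 - t0)))
        return out

    def steps(self) -> List[Tuple[float, float]]:
        """Idealized jumps ``(time, increment)`` encoded by repeated times."""
        out = []
        for (t0, v0), (t1, v1) in zip(self.nodes[:-1], self.nodes[1:]):
            if t1 == t0 and v1 != v0:
                out.append((t0, v1 - v0))
        return out

    def value(self, t) -> np.ndarray:
        """Controlled variable at times ``t`` (constant after last node)."""
        t = np.asarray(t, dtype=float)
        times = np.array([n[0] for n in self.nodes])
        vals = np.array([n[1] for n in self.nodes])
        return np.interp(t, times, vals)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"controlled": self.controlled, "nodes": [list(n) for n in self.nodes]},
            **kwargs,
        )

    @classmethod
    def from_json(cls, text: str) -> "LoadingProtocol":
        d = json.loads(text)
        return cls(d["controlled"], tuple(tuple(n) for n in d["nodes"]))


@dataclass
class MechanicalTimeSeries:
    """Sampled (time, strain, stress) record from experiment or simulation."""

    time: np.ndarray
    strain: Optional[np.ndarray] = None
    stress: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) < 0):
            raise ValueError("time must be non-decreasing")
        for name in ("strain", "stress"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=float)
                if col.shape != self.time.shape:
                    raise ValueError(f"{name} and time must have equal length")
                setattr(self, name, col)


def _branch_ramp_integral(params: FractionalModelParams, u: np.ndarray) -> np.ndarray:
    """Running integral of the dissipative-branch relaxation modulus.

    ``R(u) = int_0^u (G(v) - k) dv``; for the fractional branch
    ``R(u) = c u^(1-beta) E_{1-beta,2-beta}(-lam u^(1-beta))``, the exact
    stress produced by a unit-rate strain ramp of age ``u``.
    """
    c, beta, eta = params.c_beta, params.beta, params.eta
    out = np.zeros_like(u)
    pos = u > 0.0
    up = u[pos]
    if beta == 0.0:
        if math.isinf(eta):
            out[pos] = c * up
        else:
            out[pos] = eta * (-np.expm1(-(c / eta) * up))
    elif math.isinf(eta):
        out[pos] = c * up ** (1.0 - beta) / _gamma(2.0 - beta)
    else:
        a = 1.0 - beta
        lam = c / eta
        out[pos] = c * up**a * mittag_leffler(-lam * up**a, a, 1.0 + a)
    return out


def _branch_modulus(params: FractionalModelParams, u: np.ndarray) -> np.ndarray:
    """Relaxation modulus of the dissipative branch alone, G(u) - k."""
    from .models import relaxation_modulus

    return relaxation_modulus(params, u) - params.k


def stress_response(
    params: FractionalModelParams, protocol: LoadingProtocol, t_grid
) -> np.ndarray:
    """Stress (Pa) produced by a strain-controlled protocol.

    Exact per-segment superposition: each constant-rate strain segment
    contributes ``rate * [R(t - t_start) - R(t - t_end)]`` with ``R`` the
    closed-form running integral of ``G - k``, plus the parallel-spring
    term ``k * strain(t)``.
    """
    if protocol.controlled != "strain":
        raise ValueError("stress_response needs a strain-controlled protocol")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("response times must be >= 0")
    sigma = params.k * protocol.value(t)
    for t0, t1, rate in protocol.segments():
        diff = _branch_ramp_integral(params, t - t0) - _branch_ramp_integral(
            params, t - t1
        )
        # differencing R across a segment much shorter than its age loses
        # all precision; the midpoint-rule derivative is then exact to O(d^2)
        old = (t - t1) > 1e8 * (t1 - t0)
        if np.any(old):
            mid = t[old] - 0.5 * (t0 + t1)
            diff[old] = (t1 - t0) * _branch_modulus(params, mid)
        sigma = sigma + rate * diff
    return sigma


def _creep_running_integral(
    params: FractionalModelParams, u: np.ndarray, tol: float = 1e-7
) -> np.ndarray:
    """``Q(u) = int_0^u J(v) dv``, the strain produced by a unit-rate
    stress ramp of age ``u``; closed form in the degenerate branches,
    Talbot inversion of ``J~(s)/s`` for the full model."""
    c, beta, eta, k = params.c_beta, params.beta, params.eta, params.k
    out = np.zeros_like(u)
    pos = u > 0.0
    up = u[pos]
    if not np.any(pos):
        return out
    if beta == 0.0:
        if math.isinf(eta):
            out[pos] = up / (c + k)
        elif k == 0.0:
            out[pos] = up / c + up**2 / (2.0 * eta)
        else:
            tau_r = eta * (k + c) / (c * k)
            out[pos] = up / k - (1.0 / k - 1.0 / (k + c)) * tau_r * (
                -np.expm1(-up / tau_r)
            )
    elif math.isinf(eta):
        if k == 0.0:
            out[pos] = up ** (1.0 + beta) / (c * _gamma(2.0 + beta))
        else:
            z = -(k / c) * up**beta
            out[pos] = up ** (1.0 + beta) / c * mittag_leffler(z, beta, 2.0 + beta)
    elif k == 0.0:
        out[pos] = up**2 / (2.0 * eta) + up ** (1.0 + beta) / (
            c * _gamma(2.0 + beta)
        )
    else:
        from .models import laplace_creep

        out[pos] = invert(lambda s: laplace_creep(params, s) / s, up, tol=tol)
    return out


def strain_response(
    params: FractionalModelParams, protocol: LoadingProtocol, t_grid
) -> np.ndarray:
    """Strain (dimensionless) produced by a stress-controlled protocol.

    Superposition of creep responses: idealized steps contribute
    ``dsigma * J(t - t_step)`` and finite-rate segments
    ``rate * [Q(t - t_start) - Q(t - t_end)]`` with ``Q`` the running
    integral of ``J``.
    """
    if protocol.controlled != "stress":
        raise ValueError("strain_response needs a stress-controlled protocol")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("response times must be >= 0")
    eps = np.zeros_like(t)
    for t_step, dsig in protocol.steps():
        u = t - t_step
        mask = u >= 0.0
        if np.any(mask):
            eps[mask] += dsig * creep_compliance(params, u[mask])
    for t0, t1, rate in protocol.segments():
        diff = _creep_running_integral(params, t - t0) - _creep_running_integral(
            params, t - t1
        )
        old = (t - t1) > 1e8 * (t1 - t0)
        if np.any(old):
            mid = t[old] - 0.5 * (t0 + t1)
            diff[old] = (t1 - t0) * creep_compliance(params, mid)
        eps = eps + rate * diff
    return eps


def cyclic_force_response(
    params: FractionalModelParams,
    amplitude: float,
    on_duration: float,
    off_duration: float,
    n_cycles: int,
    points_per_phase: int = 60,
    ramp_time: float = 0.0,
) -> MechanicalTimeSeries:
    """Peak-normalized displacement under on/off constant-force cycles.

    Builds the rectangular stress protocol (idealized steps by default,
    fast ramps when ``ramp_time > 0``), computes the strain response and
    divides by its value at the end of the first on-phase — the probe
    calibration is unknown in bead-based micro-rheology, so only the
    normalized shape is meaningful.  The four published variants are
    selected through ``params``: lone spring-pot, spring-pot + dashpot
    (k = 0), the full model, and the full model with reduced ``k``.
    """
    protocol = LoadingProtocol.cyclic(
        amplitude, on_duration, off_duration, n_cycles, ramp_time=ramp_time
    )
    period = on_duration + off_duration
    t = np.concatenate(
        [
            c * period
            + np.concatenate(
                [
                    np.linspace(0.0, on_duration, points_per_phase, endpoint=False),
                    np.linspace(
                        on_duration, period, points_per_phase, endpoint=False
                    ),
                ]
            )
            for c in range(n_cycles)
        ]
        + [np.array([n_cycles * period])]
    )
    # make sure the normalization instant is on the grid
    t = np.unique(np.concatenate([t, [on_duration]]))
    eps = strain_response(params, protocol, t)
    ref = eps[np.searchsorted(t, on_duration)]
    if ref == 0.0:
        raise ValueError("zero response at end of first on-phase")
    return MechanicalTimeSeries(
        time=t,
        strain=eps / ref,
        stress=protocol.value(t),
        meta={
            "protocol": json.loads(protocol.to_json()),
            "normalization": "first-peak",
            "amplitude_pa": amplitude,
        },
    )
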