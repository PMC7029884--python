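"""Seeded generators of synthetic experiments matching the published protocols.

No raw experimental curves ship with the package, so every fitting and
prediction stage is exercised on synthetic data built from the model itself:
a strain ramp at the experimental rate followed by a hold (stress
relaxation), a stress held constant after a short loading phase (creep),
and oscillatory sweeps.  Noiseless output equals the response module
bit-for-bit; measurement noise is multiplicative Gaussian by default
(optionally plus additive), seeded and reproducible.

Default conditions are the monolayer-scale protocol: 20 % strain amplitude
(inside the ~30 % linear domain), 75 %/s loading rate, 60 s hold, creep
loads of 170 or 470 Pa; sampling is uniform during ramps and log-spaced
during holds, matching how the short-time power law and long-time plateau
are resolved experimentally.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .models import FractionalModelParams, complex_modulus
from .response import LoadingProtocol, MechanicalTimeSeries, stress_response, strain_response

__all__ = [
    "NoiseSpec",
    "SamplingSpec",
    "generate_relaxation",
    "generate_creep",
    "generate_oscillatory",
    "LINEAR_STRAIN_LIMIT",
    "CREEP_LOAD_PRESETS_PA",
]

LINEAR_STRAIN_LIMIT = 0.30
CREEP_LOAD_PRESETS_PA = (170.0, 470.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description; identical spec + seed => identical data."""

    multiplicative_sd: float = 0.01
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.multiplicative_sd == 0.0 and self.additive_sd == 0.0:
            return values
        rng = np.random.default_rng(self.seed)
        out = values * (1.0 + self.multiplicative_sd * rng.standard_normal(values.shape))
        if self.additive_sd > 0.0:
            out = out + self.additive_sd * rng.standard_normal(values.shape)
        return out


@dataclass(frozen=True)
class SamplingSpec:
    """Grid layout: uniform through the ramp, log-spaced through the hold."""

    n_ramp: int = 20
    n_hold: int = 180
    t_min_after_ramp: float = 1e-3  # s, first hold sample after ramp end

    def grid(self, t_ramp: float, duration: float) -> np.ndarray:
        hold = t_ramp + np.logspace(
            math.log10(self.t_min_after_ramp), math.log10(duration - t_ramp), self.n_hold
        )
        if t_ramp > 0.0 and self.n_ramp > 0:
            ramp = np.linspace(0.0, t_ramp, self.n_ramp, endpoint=False)[1:]
            return np.concatenate([ramp, hold])
        return hold


def generate_relaxation(
    params: FractionalModelParams,
    strain_amplitude: float = 0.20,
    ramp_rate: float = 0.75,
    hold_duration: float = 60.0,
    sampling: SamplingSpec = SamplingSpec(),
    noise: NoiseSpec = NoiseSpec(),
    t_grid=None,
    ideal_step: bool = False,
) -> MechanicalTimeSeries:
    """Ramp-and-hold stress-relaxation experiment (noisy stress).

    Warns — but proceeds — if the amplitude exceeds the ~30 % linear
    domain.  ``t_grid`` overrides the sampling layout entirely.
    ``ideal_step=True`` replaces the loading ramp with an idealized step,
    i.e. ``sigma = eps0 G(t)`` (times must then be strictly positive).
    """
    if strain_amplitude <= 0 or ramp_rate <= 0:
        raise ValueError("amplitude and ramp rate must be positive")
    if strain_amplitude > LINEAR_STRAIN_LIMIT:
        warnings.warn(
            f"strain amplitude {strain_amplitude:.2f} exceeds the ~"
            f"{LINEAR_STRAIN_LIMIT:.0%} linear domain of the model"
        )
    t_ramp = 0.0 if ideal_step else strain_amplitude / ramp_rate
    protocol = LoadingProtocol.ramp_hold(strain_amplitude, ramp_rate, hold_duration)
    t = (
        np.asarray(t_grid, dtype=float)
        if t_grid is not None
        else sampling.grid(t_ramp, t_ramp + hold_duration)
    )
    if ideal_step:
        from .models import relaxation_modulus

        sigma = strain_amplitude * relaxation_modulus(params, t)
        strain = np.full(t.shape, strain_amplitude)
    else:
        sigma = stress_response(params, protocol, t)
        strain = protocol.value(t)
    return MechanicalTimeSeries(
        time=t,
        strain=strain,
        stress=noise.apply(sigma),
        meta={
            "kind": "relaxation",
            "ideal_step": ideal_step,
            "truth_params": params.to_dict(),
            "protocol": json.loads(protocol.to_json()),
            "ramp_rate": ramp_rate,
            "strain_amplitude": strain_amplitude,
            "noise": {
                "multiplicative_sd": noise.multiplicative_sd,
                "additive_sd": noise.additive_sd,
                "seed": noise.seed,
            },
        },
    )


def generate_creep(
    params: FractionalModelParams,
    stress_level: float = CREEP_LOAD_PRESETS_PA[0],
    duration: float = 120.0,
    ramp_duration: float = 0.5,
    sampling: SamplingSpec = SamplingSpec(),
    noise: NoiseSpec = NoiseSpec(),
    t_grid=None,
) -> MechanicalTimeSeries:
    """Creep experiment: stress held constant after a short loading ramp
    (``ramp_duration = 0`` gives the idealized step); strain is the noisy
    observable."""
    if stress_level <= 0:
        raise ValueError("stress level must be positive")
    if ramp_duration < 0:
        raise ValueError("ramp duration must be >= 0")
    if ramp_duration > 0:
        protocol = LoadingProtocol.ramp_hold(
            stress_level, stress_level / ramp_duration, duration - ramp_duration,
            controlled="stress",
        )
    else:
        protocol = LoadingProtocol.step(stress_level)
    t = (
        np.asarray(t_grid, dtype=float)
        if t_grid is not None
        else sampling.grid(ramp_duration, duration)
    )
    eps = strain_response(params, protocol, t)
    return MechanicalTimeSeries(
        time=t,
        strain=noise.apply(eps),
        stress=protocol.value(t),
        meta={
            "kind": "creep",
            "truth_params": params.to_dict(),
            "protocol": json.loads(protocol.to_json()),
            "stress_level": stress_level,
            "noise": {
                "multiplicative_sd": noise.multiplicative_sd,
                "additive_sd": noise.additive_sd,
                "seed": noise.seed,
            },
        },
    )


def generate_oscillatory(
    params: FractionalModelParams,
    omega_grid,
    noise: NoiseSpec = NoiseSpec(),
):
    """Oscillatory sweep: returns ``(omega, G' noisy, G'' noisy)``.

    Independent multiplicative noise on each modulus (separate substreams
    of the seeded generator), as in AFM-style dynamic measurements.
    """
    w = np.asarray(omega_grid, dtype=float)
    if np.any(w <= 0):
        raise ValueError("omega grid must be positive")
    gp, gpp = complex_modulus(params, w)
    if noise.multiplicative_sd == 0.0 and noise.additive_sd == 0.0:
        return w, gp, gpp
    rng = np.random.default_rng(noise.seed)
    gp_n = gp * (1.0 + noise.multiplicative_sd * rng.standard_normal(w.shape))
    gpp_n = gpp * (1.0 + noise.multiplicative_sd * rng.standard_normal(w.shape))
    if noise.additive_sd > 0.0:
        gp_n = gp_n + noise.additive_sd * rng.standard_normal(w.shape)
        gpp_n = gpp_n + noise.additive_sd * rng.standard_normal(w.shape)
    return w, gp_n, gpp_n
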