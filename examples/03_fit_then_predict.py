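"""The fit-then-predict workflow: relaxation in, creep band out.

Generates a noisy stress-relaxation experiment (1 % multiplicative noise),
fits the four parameters, then predicts the creep response to a 170 Pa step
with a 95 % Monte-Carlo confidence band — no further fitting — and checks
the band against the true creep curve.
"""

import numpy as np

from rheofract import (
    FractionalModelParams,
    LoadingProtocol,
    NoiseSpec,
    creep_compliance,
    fit_relaxation,
    generate_relaxation,
    predict_with_bands,
)

truth = FractionalModelParams(c_beta=200.0, beta=0.3, eta=1000.0, k=100.0)
grid = np.logspace(-1.5, 3.0, 200)
data = generate_relaxation(
    truth, noise=NoiseSpec(multiplicative_sd=0.01, seed=42), t_grid=grid,
    ideal_step=True,
)
fit = fit_relaxation(data, assume_step=True, n_starts=3, seed=42)

names = ("c_beta", "beta", "eta", "k")
print("fitted parameters (truth in brackets):")
for name, se, tv in zip(names, fit.standard_errors,
                        (truth.c_beta, truth.beta, truth.eta, truth.k)):
    val = getattr(fit.params, name)
    print(f"  {name:7s} = {val:10.3f} +/- {se:8.3f}   [{tv}]")

t_pred = np.logspace(-1, np.log10(120.0), 40)
band = predict_with_bands(
    fit, LoadingProtocol.step(170.0), t_pred, coverage=0.95, seed=42
)
truth_curve = 170.0 * creep_compliance(truth, t_pred)
inside = (truth_curve >= band.lower) & (truth_curve <= band.upper)
print()
print(f"95 % creep band from the relaxation fit: true curve inside at "
      f"{100 * inside.mean():.0f} % of {inside.size} grid points")
print(f"predicted strain at t = 120 s: {band.central[-1]:.3f} "
      f"(band {band.lower[-1]:.3f} .. {band.upper[-1]:.3f}; truth {truth_curve[-1]:.3f})")
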