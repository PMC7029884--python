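# Methods

## The constitutive model

The material is a linear viscoelastic network: a *fractional Maxwell*
branch — spring-pot `(c_β, β)` in series with a dashpot `η` — in parallel
with a spring `k`.  The spring-pot obeys `σ = c_β d^β ε/dt^β`; its response
to any step is a power law, and the hereditary (convolution) integral
defining the fractional derivative is what produces the strong history
dependence of power-law rheology.  Because the network is linear, every
response follows from Boltzmann superposition, and all four parameters are
material properties independent of the loading protocol.

Closed forms used throughout:

* relaxation modulus
  `G(t) = c_β t^-β E_{1-β,1-β}(-(t/τ₁)^{1-β}) + k`, with
  `τ₁ = (η/c_β)^{1/(1-β)}`;
* Laplace-domain moduli
  `G̃(s) = k/s + η/(1+(τ₁ s)^{1-β})` and `J̃ = 1/(s² G̃)` (the linear
  reciprocity `G̃ J̃ = s^-2`);
* complex modulus from the network impedances
  `G*(ω) = k + iωη·c_β(iω)^β/(iωη + c_β(iω)^β)`.  This expression is
  derived here from the topology (series impedances add as compliances,
  parallel as moduli) and validated in the tests against the analytic
  continuation `s G̃(s)|_{s=iω}`;
* creep compliance of the degenerate branches:
  `J = t^β/(c_β Γ(1+β))` (spring-pot), `+ t/η` (fractional Maxwell fluid),
  `(1/c_β) t^β E_{β,1+β}(-(k/c_β)t^β)` (fractional Kelvin–Voigt), and the
  textbook exponential forms at `β = 0`.  The full model's `J(t)` is
  numerically inverted from `J̃`.

`β = 1` is excluded (the relaxation kernel would involve the ill-defined
`E_{0,0}`); the admissible range is capped at `1 − 1e-6`.  `k = 0` is the
fluid limit (no plateau, handled in closed form rather than through the
`k > 0` Laplace expression, which is singular there); `η = ∞` removes the
dashpot.

### Characteristic times and creep regimes

`τ₂ = η/k` and `ξ = τ₁/τ₂` classify creep: `ξ < 1` dissipative-first
(power law → viscous flow → plateau), `ξ > 1` spring-first (fractional
Kelvin–Voigt behaviour with time `τ₂′ = (c_β/k)^{1/β} =
τ₁^{(β-1)/β} τ₂^{1/β}`; `τ₁` becomes irrelevant), `ξ ≈ 1` simultaneous.
The "≈" band is implemented as `ξ ∈ [1−δ, 1/(1−δ)]` with `δ = 0.25`, a
symmetric-on-the-log-axis convention chosen here.  Undefined quantities
(`τ₂` with `k = 0`, `τ₂′` with `β = 0`) are reported as `None`, never 0.

Two quantitative caveats, both properties of the model rather than of this
implementation, and both asserted as such in the tests:

* the local log-log creep slope approaches the viscous value 1 only in the
  `ξ → 0` limit (measured: max slope 0.93 at `ξ = 10⁻³`, 0.59 at
  `ξ = 0.1`, β = 0.3) — the fractional transitions are power-law-broad;
* the fractional-Maxwell relaxation steepens beyond `τ₁` (the
  exponential-like cut-off regime) but terminates in the algebraic tail
  `t^-(2-β)` of the Mittag-Leffler kernel, so "decays faster than any
  power law" holds only in the intermediate window around `τ₁`.

### Short-time power law

`G − k → c_β t^-β/Γ(1−β)` with leading relative correction
`(t/τ₁)^{1-β} Γ(1−β)/Γ(2−2β)`.  On the window `[10⁻⁴, 10⁻²] τ₁` the
fitted slope is within 0.01 of `−β` for `β ≲ 0.25`; larger β needs deeper
windows (the tests assert the convergence explicitly).

### Relaxation spectrum

`H(τ) = (1/π) Im[s G̃(s)]` at `s = (1/τ) e^{i(π−ε)}` — the standard
continuation onto the upper lip of the branch cut, with offset angle
`ε = 10⁻³` by default.  For `β > 0` the branch-point structure makes the
continuation smooth (the FMM pole lies off the principal sheet); `β = 0`
has a true pole on the cut, rendered as a Lorentzian of width ε whose
log-integral recovers the arm stiffness `c`.  The spring-pot limit
reproduces the known `H = (c_β/π) sin(βπ) τ^-β`; for the full model H is
quasi-flat for small β and decays beyond the cut-off `τ₁`.

### Master curve

Relaxation records are normalized as `(t/τ₁, (G−k) τ₁^β/c_β)`; substituting
`G` shows the transformed curve depends only on `t/τ₁` and β, so materials
sharing β collapse exactly.  Any normalization with that property would do;
this one makes the reduced curve `x^-β E_{1-β,1-β}(−x^{1-β})`.

## Numerics

### Mittag-Leffler kernel

`E_{a,b}(z)` on the real line, vectorised, three regimes selected by
`u = |z|^{1/a}` (named constants in `mittag_leffler.py`):

* `u ≤ 10` or `z ≥ 0`: float64 power series in log-space (the largest term
  exceeds the sum by ~`e^u`, harmless here);
* `10 < u <` 26 (40 for `a > 0.85`): Talbot-contour evaluation of
  `L^{-1}[s^{a-b}/(s^a − z)](1)` — for `z < 0` the pole sits off the
  principal sheet — cross-checked at two node counts, falling back to the
  Gorenflo–Loutchko–Luchko spectral integral (adaptive quadrature, with
  `b` reduced into `(0,1]` by the standard recurrences) when they disagree,
  and used directly for `a > 0.85` where the quasi-pole approaches the
  contour;
* beyond, with additionally `|z| ≥ 16`: the algebraic asymptotic expansion
  `−Σ z^{-n}/Γ(b−an)`, truncated at its smallest term *envelope* (the raw
  coefficients oscillate through reflection-formula zeros).  The `|z|`
  floor matters at small `a`, where `u` explodes while the expansion
  variable `1/z` does not.

`a = 1` routes to `exp`/`expm1` closed forms for `b ∈ {1, 2}`.  Validated
to ≤ 5e-9 relative error against an independent arbitrary-precision series
on the grid `a ∈ [0.1, 1]`, `b ∈ {a, 1, 2−a}`, `z ∈ [−50, 2]`.

### Inverse Laplace transform

Fixed-Talbot (Abate–Valkó) with `M = 28` nodes and contour scale
`r = 2M/(5t)` — optimal in double precision, where accuracy is bounded by
cancellation against `e^{2M/5}`.  All transforms inverted here are
analytic off the negative real axis, Talbot's design case; poles *on* the
cut (the β = 0 creep) are enclosed by the contour.  A-posteriori error
estimate: relative difference between `M` and `M+12` nodes; points failing
the tolerance (typically values decayed far below the curve scale) are
re-evaluated with an arbitrary-precision Talbot contour at two sizes
(degree 40/dps 35 vs 56/45) and the inversion *fails loudly* if those
disagree too.  Below `t = 10⁻⁸ τ₁` the creep inversion is replaced by the
exact short-time spring-pot series.

### Response to piecewise-linear protocols

Strain control: each constant-rate segment contributes
`rate·[R(t−t₀) − R(t−t₁)]` with the exact branch antiderivative
`R(u) = c_β u^{1-β} E_{1-β,2-β}(-(u/τ₁)^{1-β})`, plus `k·ε(t)`.  Stress
control: steps contribute `Δσ·J(t−t_s)` and ramps use the running integral
`Q(u) = ∫J`, closed-form in the degenerate branches and `L^{-1}[J̃/s]`
otherwise.  When a segment is much shorter than its age
(`age > 10⁸ × duration`), the difference of running integrals loses all
precision and is replaced by the midpoint-rule derivative
`duration × G(t−t_mid)` (error `O(duration²)`).  Strain steps are realized
as fast ramps at the experimental rate (default 75 %/s, time zero at ramp
start); stress steps may be idealized, since the bead-pulling closed forms
(`2^β − 1` first-cycle residual, etc.) assume them.

## Fitting

* **Objective** — relative least squares (`model/data − 1`); relaxation
  data are first resampled onto a log-spaced grid (200 points) so the
  power-law decade(s) and the plateau carry comparable weight.  The hold
  phase is fitted by default (`include_ramp=False`); the model stress is
  ramp-convolved unless `assume_step=True`.
* **Parameterization** — `log c_β, β, log η, log k` internally; bounds are
  a wide data-scaled box.  Fixed-parameter masks support sub-model fits.
* **Optimizer** — bounded trust-region least squares with 8 multi-starts
  (seeded log-normal perturbations of a data-driven heuristic guess: β
  from the short-time slope, k from the tail, c_β from the intercept, η
  from the apparent cut-off).  The heuristic start is itself included, so
  the returned objective never exceeds the initial one.
* **Uncertainties** — Gauss–Newton covariance `s²(JᵀJ)⁻¹` at the optimum
  in internal coordinates, mapped to natural units by the delta method.
  Parameters within a factor ~2 of a bound (0.01 absolute for β) are
  flagged `bound_hit` — the symptom of structural unidentifiability (e.g.
  η when the data never reach τ₁); the fit reports rather than fails.
* **Prediction bands** — seeded Monte-Carlo: 400 draws from the Gaussian
  approximation in log coordinates (which respects positivity), truncated
  to admissible ranges, pushed through the response module; the band is
  the pointwise quantile envelope at the requested coverage.  A ±z·SE
  corner envelope was considered and rejected: it ignores parameter
  correlations, which are strong (c_β–η in particular).

## Synthetic data

The generators emulate the laboratory protocols: strain ramp at 75 %/s to
20 % amplitude (inside the ~30 % linear domain; exceeding it warns) then a
60 s hold, sampled uniformly through the ramp and log-spaced through the
hold; creep as a stress held after a short ramp (or an idealized step),
with 170/470 Pa presets; oscillatory sweeps over four decades.  Default
truth parameters `c_β = 200 Pa·s^β, β = 0.3, η = 1000 Pa·s, k = 100 Pa`
give `τ₁ ≈ 10 s`, `τ₂ = 10 s`, `ξ ≈ 1` — monolayer-scale values chosen
once: stresses of order 10²–10³ Pa, plateau reached within a minute, and
the near-simultaneous regime reported for untreated epithelial sheets.

Noise is multiplicative Gaussian (default 1 %, independent per sample;
oscillatory data get independent streams for G′ and G″), optionally plus
additive noise — a deliberately idealized instrument model.  It captures
the roughly constant *relative* scatter of force-transducer data but none
of drift, creep of the instrument, correlated vibration noise, or active
biological remodeling.  Passing recovery tests therefore demonstrates the
estimator is correct and well-conditioned under the stated conditions, not
that real monolayer data will yield sub-percent parameter errors.

Recovery studies in the tests and acceptance script use 200 log-spaced
points spanning `[10⁻² τ₁, 10² τ₂]`, 20 noise seeds, 3–5 multi-starts per
fit — sizes chosen to give stable medians on a single core in minutes.

## Known limitations

* Linear theory throughout: no warning is raised if simulated strains
  leave the ~30 % linear domain (only the generator amplitude is checked).
* No pre-stress/active-tension term; no plasticity.
* The spectrum continuation needs `ε` tuning if β is exactly 0 and the
  Lorentzian peak must be resolved.
* Oscillatory fits of pure power-law data leave `η`, `k` unidentified;
  they settle at large/small interior values (flagged through `tau1` far
  outside the window and a negligible `k`), not exactly on the bounds.
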