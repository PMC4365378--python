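# Methods

## Physical setting and model structure

A disk of collagen gel (cross-section `A0 ≈ 700 mm²`, reference extension
`e0`) is compressed between platens; the machine commands the extension
`e(t)` and a load cell records `y(t)` in newtons. The gel is modeled
quasi-statically (no inertia) as two Maxwell bodies in parallel — a
second-order viscoelastic system with relaxation times `τ1 < τ2` and spring
constants `g1, g2 ≥ 0` — excited through a static nonlinearity:

* **Model 1 (Mooney-Rivlin-inspired).** The memoryless spring extension
  `e′(λ) = (C1 + C2/λ)(λ² − 1/λ)`, `λ = e/e0`, drives
  `τ_i ẋ_i = e′ − x_i`; the load is `y = [g1(e′−x1) + g2(e′−x2)]·e0/e`.
  The factor `e0/e = 1/λ` converts between the Eulerian stress σ and the
  stress measure `T = σ·e0/e`. `C2 = 0` is the Neo Hookean variant.
* **Model 2 (Hammerstein).** `u′ = p0ε³ + p1ε² + p2ε` with the signed strain
  `ε = (e−e0)/e` feeds the linear block
  `ÿ + a1ẏ + a2y = b0ü′ + b1u̇′`, realized in the canonical state-space form
  whose input matrix avoids differentiating `u′`. The Maxwell and
  transfer-function parameterizations are exactly interconvertible
  (`maxwell_to_tf`/`tf_to_maxwell`) whenever the poles are real, distinct
  and negative.

Units: time s, length mm, force N, cross-section mm². The hyperelastic
constants and `e′` are treated as stress-like and the `g_i` absorb the area
factor, so the simulated output is directly the measured load. Signs follow
the compression convention: `e < e0`, hence `λ < 1` and `ε < 0`; protocol
descriptors use the positive engineering-strain magnitudes an operator
programs, and the conversion to signed strain happens when a model input is
built.

Degenerate `τ1 = τ2` is rejected rather than handled by a confluent form:
the structure is explicitly a two-distinct-body model, and the estimators
treat a repeated pole as a failed identification.

## Simulation

Given the memoryless block output, both models are linear in their states,
so the default integrator is an exact exponential first-order-hold
recursion: the input to each state equation is interpolated linearly
between samples and the one-step transition is computed from the matrix
exponential (scalar for model 1, 2×2 for the linear block). On uniform
grids the recursion diagonalizes into two scalar IIR filters and runs
through `scipy.signal.lfilter`. Model 1 additionally sub-samples each
interval (default `refine=2`) because `e′` is nonlinear in `e`; this keeps
the step-halving change of the output below 1e-6 in relative sup-norm on
the default protocols. A stiff-capable variable-step alternative
(`method="lsoda"` via `scipy.integrate.solve_ivp`) is retained and
cross-checked against the default path in the tests. Initial states are
zero — the sample is unloaded at `t = 0`, which every generated protocol
honors by starting at `e = e0`.

Simulating an unstable transfer function warns but proceeds (interim
estimates during identification can wander); `e ≤ 0` anywhere in a record
is a hard error, as the model-1 output divides by `e`.

## Synthetic protocol generator

The generator emulates the test campaign of a desktop materials tester:

* ramps at 0.1–1 mm/min to 20% engineering strain,
* cyclic tests: approach ramp to the mean of the cycle bounds, then
  triangular excursions mean → 25% → 15% → mean at constant crosshead speed
  (eight cycles by default),
* step relaxations: 10 mm/min to 25% or 50% strain, then an 1800 s hold.

Sampling defaults to 10 Hz for ramps/cycles and 1 Hz for relaxations —
coarse enough to keep records at desk scale, fine enough to resolve the
fastest relaxation time of interest (≈ 1 s) marginally; both are
configurable and every study states its rate. Measurement noise is
additive i.i.d. Gaussian on the load only (the strain is machine-commanded),
with standard deviation given absolutely or as a fraction of the clean peak
load (1% in all default studies). Datasets round-trip through CSV with a
`# key = value` metadata header recording full provenance (protocol, model,
parameters, noise, seed), so a file is regenerable from its own header.

What the generator does *not* emulate: machine compliance, sample slippage,
temperature effects, strain-measurement error, non-Gaussian or correlated
load noise, and sample-to-sample biological variability. Passing
self-consistency tests therefore demonstrates that the estimators invert
the models correctly under the stated noise model — not that the models
describe any particular real gel.

## Linear continuous-time identification

`fit_linear_ct` implements a simplified refined instrumental-variable
scheme for the second-order structure with zero DC gain:

1. **Initialization.** State-variable filtering with `F_i(s) = s^i/(s+ω_c)²`
   produces filtered derivative surrogates of `u` and `y` without
   differentiating noise; least squares on
   `y_f″ = −a1 y_f′ − a2 y_f + b0 u_f″ + b1 u_f′` gives a first estimate.
   Because no single cutoff suits both the cyclic regime (τ ≈ 1–20 s) and
   the long relaxations (τ up to 180 s), the cutoff sweeps eight
   log-spaced values between `4/T` (record length `T`) and half the Nyquist
   rate, and the stabilized candidate with the smallest output error wins.
2. **Refinement.** Iteratively: simulate the current model to get a
   noise-free output surrogate, prefilter everything with
   `1/(s² + â1 s + â2)`, and solve the instrumental-variable normal
   equations with instruments built from the simulated output. Iterate to a
   relative parameter change below 1e-9 (cap 100 iterations; non-convergence
   is flagged, not raised). Unstable interim estimates are projected back
   into the left half plane by reflecting the offending poles, with a
   warning.

All continuous-time filtering uses the same exact FOH state-space machinery
as the simulators, with zero initial filter states (valid because the
records start from rest). A constant input raises an excitation error.

## Grey-box prediction-error minimization

`fit_greybox` minimizes the sum of squared output errors by a
Levenberg-Marquardt loop with forward-difference Jacobians (step
`√eps·max(|θ|, 1)`), multiplicative damping (÷10 on acceptance, ×10 on
rejection), and the rule that a trial step whose simulation fails —
non-finite output, invalid relaxation times — is rejected exactly like an
uphill step. Accepted iterates never increase the loss (asserted by a test
on the recorded loss history). Convergence: relative loss decrease below
`tol` (default 1e-9) on an accepted step.

Model 1's output is invariant under `(C1, C2, g1, g2) → (kC1, kC2, g1/k,
g2/k)`; the Hammerstein model under `(p, g) → (kp, g/k)`. The fits
therefore pin one scaled parameter (`C2` for model 1, `C1` for the
Neo Hookean variant, `g1` for the Hammerstein model), and the model-1 time
constants are by default inherited from the prior linear fit (releasing
them is possible but departs from the two-stage workflow). The ridge and
the necessity of the normalization are demonstrated numerically in the
test suite: unnormalized fits started at two ridge-related points reach
indistinguishable loss with very different parameters.

`scipy.optimize.least_squares(method="lm")` solves the same problem in a
test as an independent cross-check of the minimizer; it is never the
implementation path.

## Metrics and diagnostics

* FIT uses the Euclidean norm over the whole record (the norm choice and
  the full-record convention are options; both defaults are stated here
  because reasonable alternatives exist — e.g. excluding the first
  compression).
* FPE is Akaike's final prediction error `(loss/N)(1+d/N)/(1−d/N)` with `d`
  the number of free parameters of the fit, computed on the cycling part of
  the identification record (the record splitter keys on the first time the
  lower cycle bound is reached).
* The Mooney-Rivlin linearization plots `σ/(λ²−1/λ)` against `1/λ`; a
  guard band `|λ−1| < 0.01` excludes the singular neighborhood of the
  reference configuration, and the excluded count is reported. For data
  generated by the hyperelastic law the intercept/slope recover `C1`/`C2`
  exactly; zero slope is the Neo Hookean signature.
* Hysteresis area is the time-ordered loop integral `∮ y dε` including the
  closing segment; the trajectory must close to a stated relative
  tolerance. It is non-negative for passive parameter sets at steady state
  and zero for a purely elastic response.

## Study configurations and problem sizes

The default cyclic study uses four samples at speeds 1.0/0.5/0.5/0.1 mm/min
(5 401 to 54 001 points at 10 Hz); the relaxation study uses 1 809- and
1 816-point records at 1 Hz. The recovery experiments run 10 noise seeds
per target at 1% load noise with initialization at twice the generating
values. These sizes were chosen to mirror the original campaign's protocol
durations while keeping any single study in the seconds-to-minutes range.
Fast unit tests use a down-scaled protocol (3 cycles at 5 Hz) that
preserves every structural feature.

## Known limitations

* The SRIVC variant here is the simplified scheme specialized to the
  second-order, zero-DC-gain structure; no model-order selection, no noise
  modeling beyond output-error, no handling of nonzero initial conditions.
* The grey-box Jacobians are numeric; analytic sensitivities would speed up
  and slightly robustify the fits.
* FPE compares structures on the same data with the same loss convention;
  it is not an absolute quality measure.
* The Hammerstein cubic with its cubic leading term extrapolates badly
  outside the strain range it was fitted on; validation inputs should stay
  within the identification range, as they do in the default studies.
* Real-data effects excluded by the noise model (drift, slippage,
  compliance) would bias the estimators in ways the synthetic studies
  cannot reveal.
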