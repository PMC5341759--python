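# Methods

## Model and inference

The package implements Gaussian generative models of sensory observations
and the neural-circuit algorithms that invert them.

**Scalar model.** A feature `v` has prior N(v_p, Σ_p); an observation `u`
is N(g(v), Σ_u).  Observation maps `g` are: `square` (v²), `identity`,
`linear_theta` (θv) and `theta_h` (θ·h(v) with h either v² or v).  The
normal observation model admits negative intensities; this simplification
is deliberate and no truncation is applied.

**Exact posterior.** `exact_posterior` evaluates ln p(v) + ln p(u|v) on a
uniform grid (inclusive endpoints; default 0.01…5.0, step 0.01, matching
the worked example's figure domain), subtracts the maximum before
exponentiating — for nonlinear g the likelihood underflows over most of the
grid — and normalizes with the trapezoidal rule.  The trapezoid/Riemann
difference is far below the 1e−6 normalization tolerance at the default
step.  If every grid point underflows to −∞ a degenerate-posterior error is
raised rather than returning NaNs.  Argmax ties break toward the smallest
grid value.

**Approximate inference.** Restricting the approximate posterior to a point
mass at φ turns inference into maximization of the negative free energy
F(φ) = ln p(u, φ); both constant terms (−ln 2π per factor) are retained so
F is exactly the log joint density.  Two routes are implemented and
cross-checked: explicit Euler gradient ascent on F, and the three-node
circuit

    dφ/dt  = ε_u g′(φ) − ε_p
    dε_p/dt = φ − v_p − Σ_p ε_p
    dε_u/dt = u − g(φ) − Σ_u ε_u

whose ε fixed points are the precision-weighted errors.  The circuit
converges to the same φ but more slowly: the coupled
excitatory–inhibitory loop is underdamped and rings before settling.

**Learning.** All parameter gradients are Hebbian at the error fixed
points: ∂F/∂v_p = ε_p, ∂F/∂Σ = ½(ε² − Σ⁻¹), ∂F/∂θ = ε_u φ or ε_u h(φ).
Learning runs one observation per trial: the circuit is integrated for a
fixed horizon T (the operational definition of convergence; an adaptive
stopping rule would complicate the circuit interpretation without changing
stationary behaviour), parameters are stepped, and estimated variances are
clipped at 1.0.  The floor prevents the error-node relaxation rate Σ from
approaching 0, where the node dynamics diverge or become arbitrarily slow.

**Multivariate and hierarchical.** With vectors of features,
g(φ̄, Θ) = Θh(φ̄) (element-wise h, linear mixing — the standard
linear-features assumption), covariances Σ, and the same rules in matrix
form; all matrix-calculus gradients are verified against central finite
differences.  Hierarchies chain p(v̄_i | v̄_{i+1}) = N(Θ_i h(v̄_{i+1}), Σ_i)
with the sensory layer clamped to the observation (the bottom boundary of
the published dynamics, made explicit here) and a fixed Gaussian prior
(v_p_top, Σ_top) closing the top (the chain's top boundary is otherwise
implicit).  φ̄ is initialized at the top-down predicted means, ε̄ at zero.
The matrix variance floor clips eigenvalues of each learned Σ at 1 and
re-symmetrizes — the natural generalization of the scalar floor.  The
numerically computed Σ⁻¹ in the learning rules is symmetrized so that Σ
updates preserve symmetry exactly.

**Local plasticity.** The Σ⁻¹ in the covariance rule is non-local (a
synapse would need weights it does not touch).  Pairing each error node
with an inhibitory interneuron,

    dε̄/dt = (φ̄_i − g_i(φ̄_{i+1})) − ē,     dē/dt = Σ ε̄ − ē,

puts the fixed point at ε̄* = Σ⁻¹·drive, ē* = drive, and the weight rule
ΔΣ = α(ε̄ēᵀ − I) is purely local with stochastic fixed point ⟨drive·driveᵀ⟩
— the drive covariance.  The subtracted "1" is the identity matrix (required
for dimensional consistency; off-diagonal targets are then raw
covariances).  The instantaneous update ε̄ēᵀ is not symmetric; Σ is
re-symmetrized after each step (its expectation is symmetric).  Stability:
the linearized system matrix [[0, −I], [Σ, −I]] has trace −1·d and, in the
scalar case, determinant Σ, so the fixed point is stable for every
positive-definite Σ; `stability_analysis` computes the spectrum explicitly.

## Synthetic data

`TrialStream` draws i.i.d. (multivariate) normal inputs with stated mean
and covariance and subtracts a constant top-down prediction to form drives.
Defaults follow the variance-learning study conditions: mean 5, variance 2,
prediction 5, 1000 trials, α = 0.01, 20 time units of inner dynamics per
trial, Σ₀ = 1 (the floor — a natural "uninformed" start; the initial value
is not otherwise pinned down).  A single seed drives each stream; the same
seed reproduces draws bit-for-bit.

What the generator does *not* emulate: temporal correlation between trials,
non-Gaussian input statistics, drifting generating parameters, and
structured natural stimuli.  Passing tests therefore show that the circuits
implement their defining fixed-point equations and recover the moments of
stationary Gaussian streams — not that they extract features from natural
images (explicitly out of scope).

## Numerical choices

- **Integrator:** fixed-step explicit Euler, dt = 0.01 everywhere by
  default (the step used in the worked examples; the circuit example states
  it only for gradient ascent but the same timescale is used for the
  three-node circuit).  Trajectories include t = 0 and the final step; an
  overflow guard (|state| > 1e8) raises an instability error naming the
  step and dt instead of propagating NaNs.
- **Variance-learning inner loop:** within a trial the (ε, e) system is
  linear with constant drive, so the state after N Euler steps is evaluated
  in closed form (x_N = −A⁻¹(I − (I + dt·A)^N)·b from rest).  This is
  algebraically the Euler iterate, not the exact ODE flow, and a test pins
  it to the explicit loop at 1e−8.  (ε, e) restart from rest each trial;
  after 20 time units the fixed point is approached to ~e⁻¹⁰, so carry-over
  would be immaterial.
- **Monte-Carlo bands:** linearizing ΔΣ = α(εe − 1) about its fixed point
  gives a stationary sd of ≈ σ²√(α/2) per weight (covariance entry (i,j):
  √((σ_ii σ_jj + σ_ij²)α/2)) with a correlation time of ≈ σ²/α trials.
  Trailing-window means over windows shorter than the correlation time
  therefore carry essentially the full stationary sd; stochastic tests use
  3× this as their acceptance band.
- **Learning-rate defaults:** 0.01 per trial for every rule (the rate
  stated for variance learning, reused globally for consistency).
- **Finite-difference oracle:** central differences; for symmetric-matrix
  arguments an optional symmetric perturbation mode perturbs (i,j) and
  (j,i) together and divides by the number of perturbed entries, matching
  the element-wise gradient convention of the analytic covariance rules.
- **Problem sizes:** property tests run hierarchies up to 4×4×4 levels,
  covariance learning at 1000–5000 trials in 1–2 dimensions, and weight
  learning at 5000 trials with 2 features — sizes at which the Monte-Carlo
  bands above are informative while the whole suite stays fast.

## Design notes

- The modulatory θ·h′(φ) pathway of the nonlinear circuit is implemented as
  the plain product in the φ-node derivative without committing to a
  specific neural realization of the modulation.
- `theta_circuit_derivatives` with θ = 1 reduces exactly to the fixed-map
  circuit (identity or square), which the tests use as a consistency check.
- The variance floor is also applied inside the local-plasticity circuit;
  strictly, the floor is only required where Σ sets an error-node
  relaxation rate, and keeping it in the interneuron circuit is an
  extension chosen for uniformity.
- Attention-style precision modulation is available simply by scaling
  entries of a learned Σ (or inhibiting interneurons); it is a
  configuration of existing operations, not a separate model.

## Known limitations

- Scalar learning with a fixed observation noise does not recover the
  *generating* variance of the stimulus stream: the stochastic fixed point
  is Σ_p = var(φ) — the variance of the *inferred* feature, which inference
  shrinks toward the prior.  The self-consistency condition
  Σ_p = gen_var·(Σ_p/(Σ_p+Σ_u))² only has a stable root above the floor
  when gen_var ≥ 4Σ_u; the tests honour this.
- Explicit Euler is first order: for ẋ = −x at dt = 0.01, T = 5 the
  relative error against e⁻⁵ is ≈ T·dt/2 = 2.5%.  Fixed points are exact,
  so converged answers do not inherit this error, but transients do.
- No spiking, no f-I nonlinearities beyond the stated node dynamics, no
  cortical-layer anatomical mapping, and no training on natural images.
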