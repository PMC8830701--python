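# Methods

## Problem and model

`crninfer` infers a sparse mass-action reaction network from noisy
time-series concentration measurements of N chemical species.  Given a
candidate ("ansatz") library of D reactions — each of order at most two on
either side — the reaction-rate equations read

    dX/dt = S_c^T (k ⊙ f(X)),      f_d(X) = ∏_reactants [X_n]^(multiplicity)

where `S_c` is the D×N complete stoichiometric matrix (reactions as rows,
net species change per row; this package stores reactions as rows and
applies the transpose, a convention documented once here) and `k ≥ 0` the
vector of unknown rate constants.  A doubled reactant contributes its
squared concentration; combinatorial factors are absorbed into `k`, so the
rate of `2A -> …` is `k[A]²`.  Network inference is variable selection on
`k`: most candidates do not occur, so `k` is sparse.

The prior on each free rate is the regularized horseshoe:

    λ_i ~ Cauchy⁺(0, 1)
    λ̃_i² = c² λ_i² / (c² + τ² λ_i²)
    k_i ~ Normal(0, τ λ̃_i) truncated to k_i ≥ 0
    c   ~ Inv-Gamma(a, b)

`τ` (fixed, dimensionless) sets the scale below which a rate counts as
absent; the heavy-tailed local scales `λ_i` let individual rates escape
shrinkage; the slab scale `c` caps the effective prior scale `τλ̃_i` of
selected rates (the plain horseshoe is the `c² → ∞` limit).  Rates are
physical and non-negative, so the Normal slab is truncated at zero —
equivalently `k_i = τλ̃_i |z_i|`, `z_i ~ N(0,1)`, which is also the
non-centered parameterization the sampler uses.  A symmetric prior would
let negative rates imitate the reverse reactions that are anyway present
in the library.

The observational model treats the ODE solution `Z(t)` as a latent
trajectory: measurements are median-unbiased multiplicative noise,

    log X̂(t_j) ~ Normal(log g(Z(t_j)), σ²),  j = 0…T,

summed over replicate trajectories when several are observed.  The
observation map `g` is the identity, a coordinate subset (partially
observed systems), or a single non-negative weighted sum.  "Log-Normal(0,
σ)" is read throughout with σ as the log-scale standard deviation — the
only reading under which the synthetic-data generator ("truth ×
exp(N(0,σ²))") and the likelihood agree.  A Poisson alternative
(`X̂ ~ Poisson(g(Z))`) is available for integer count data.  σ carries a
half-Normal(0, 1) prior by default (weakly informative on the scales of
both bundled fixtures) and is inferred; it can be widened in the config.

A derivative-based variant replaces the latent ODE with second-order
finite-difference derivative estimates regressed on the mass-action basis
(`dX̂/dt(t_j) ~ Normal(S_c^T(k ⊙ f(X̂_j)), 1)`, unit scale by convention,
optionally estimated).  It is much faster — no ODE solves — but requires
fully observed species and inherits derivative-estimation bias, which is
exactly the failure mode the latent variant removes on sparse grids.

Initial latent state: by default `Z(t_0)` is fixed to the first
observation (adequate for dense, low-noise grids).  With
`init_state_mode="inferred"` it gets a log-normal prior centered at the
first observation (log-scale sd 0.5); on sparse noisy grids this matters —
anchoring the trajectory to a single noisy measurement mis-centers every
subsequent prediction, and the sparse-grid analyses here use the inferred
mode.

## Computation

The log posterior and its exact gradient are evaluated by integrating the
ODE together with its forward sensitivities `dZ/dk` (and `dZ/dZ0` when the
initial state is inferred) using a fixed-step classical Runge-Kutta scheme
compiled with numba.  A fixed-step scheme is used during inference so that
the returned gradient is the exact derivative of the discretized solution
the density itself uses.  The step count is set per dataset (`nsub`
sub-steps per observation interval; defaults aim at ≈150 steps across the
observation window, which reproduces the adaptive-solver log density to
≲0.01 on the bundled fixtures).  Data generation and stand-alone
simulation use adaptive RK45 (rtol 1e-6, atol 1e-8) with an LSODA fallback
for stiff systems.  Non-finite or exploding states map to a -inf log
density (the proposal is rejected) rather than aborting a chain.

Sampling is dynamic Hamiltonian Monte Carlo with the No-U-Turn criterion,
multinomial state selection, dual-averaging step-size adaptation (target
acceptance 0.85) and windowed mass-matrix estimation — diagonal by
default, optionally dense (full covariance, shrunk toward its diagonal)
to decorrelate jointly-identified rates.  Two guards keep adaptation
stable: windows holding fewer than 50 samples never replace the current
metric, and the dense estimate is used only when a window holds more
samples than there are parameters; short-window dense estimates are noisy
enough to steer chains into spurious regions.
Divergent transitions (Hamiltonian error > 1000) are counted and reported.
Mean-field Gaussian variational inference (reparameterized gradients,
Adam) is available both as a standalone approximation and as the
initializer for MCMC.

Because τ is deliberately tiny, the shrunken region of the posterior is an
extremely long funnel: a chain started cold at jittered unconstrained
values must diffuse ~18 log-units up the local scales before the
likelihood takes hold, which does not happen in any reasonable budget.
Each chain is therefore initialized from a non-negative least-squares fit
of the derivative-based regression (the package's own fast variant, run
first exactly as recommended for exploratory use): unconstrained
coordinates are jittered Uniform(-2, 2) and local log-scales are lifted so
the implied rates match the point estimate; a short variational pre-fit
then supplies the start point and initial mass matrix.  Chains still
disperse across modes — on the auto-regulation problem different chains
settle into different sparse networks — and all post-processing treats
modes separately.

Numerical safeguards: λ is clamped at 1e120 before squaring (τλ̃ has
saturated at c long before; unclamped, the slab-gradient overflows and
injects spurious divergences), and model values pass through a 1e-10 floor
before the log inside the likelihood only — never inside the dynamics, so
solver trouble is not masked.

## Pruning and mode handling

The horseshoe is continuous, so no rate is exactly zero.  Reaction i is
pruned when `P(τλ̃_i < δ) > p0`, estimated from the draws; defaults
δ = 1e-3, p0 = 0.90.  Retained rates are reported as posterior medians
with central 5–95% intervals (interval type is a package choice).
Retained rates are not re-fit conditional on the pruned structure by
default; the unconditional medians are reported.

Chains are grouped by the support set their own draws imply under the
pruning rule; groups are ordered by mean within-group log posterior and
reported separately.  Split-R̂ (each chain halved) and bulk ESS are
computed with arviz; on multimodal fits they are meaningful only within a
mode group — cross-mode R̂ is expected to fail and is not a defect.

`sensitivity_sweep` tabulates retained-set size over a (δ, p0) grid,
supporting the recommended calibration: thresholds such that admitting
more reactions no longer improves the fit while removing reactions
degrades it.  The same principle governs τ: small enough that pruning
removes most of the library while the retained network still maintains
the dynamics.  The bundled predator-prey configuration uses τ = 1e-8 with
c ~ Inv-Gamma(4, 4); the auto-regulation desk configuration uses τ = 1e-6
with c ~ Inv-Gamma(5, 25).  In the auto-regulation experiment the noise
scale σ is additionally fixed at its known value (0.07): when σ is free, a
sparse mode that misfits the dynamics can inflate σ to absorb the
residuals and remain competitive with well-fitting modes; with the
measurement scale treated as known — realistic when the assay's noise is
characterized — every surviving mode must genuinely reproduce the
dynamics.  The predator-prey fits keep σ inferred.

## Baseline

The derivative-regression baseline minimizes

    (1/2T) Σ_j ‖dX̂/dt(t_j) − S_c^T(k ⊙ f(X̂_j))‖² + αλ_mix‖k‖₁ + α(1−λ_mix)‖k‖₂²,  k ≥ 0,

via FISTA with a non-negativity prox (tolerance 1e-8 relative objective
change); with `k ≥ 0` the ℓ1 term is simply Σk_i.  The grid search spans
α ∈ logspace(1e-6, 10) × λ_mix ∈ {0, .25, .5, .75, 1} (ranges are package
defaults) and selects, among grid points whose thresholded active set has
the minimal nonzero size, the best data term.  A post-fit threshold
converts the estimate into an active set; 1e-3 suits the predator-prey
scale (one true rate is 0.01), 1e-2 the auto-regulation scale.

## Synthetic fixtures

Two generators reproduce the study systems exactly from their printed
parameters and are pure functions of (parameters, seed):

* **Lotka-Volterra** (prey Y, predator P): `Y -> 2Y` (1.0),
  `P + Y -> 2P` (0.01), `P -> 0` (0.3), X(t0) = (P=50, Y=100), observed on
  [0, 15] at dt ∈ {0.2, 1, 2} (76/16/8 points) with σ = 0.2 noise, inside
  a fixed 16-candidate library with the true reactions at indices 2–4.
* **Prokaryotic auto-regulation** (g, P2, gP2, r, P): the 8-reaction
  repression/transcription/translation/dimerization/degradation scheme
  with k = (0.5, 1, 0.15, 1, 0.5, 0.5, 1.5, 0.3), all species starting at
  20, observed on [0, 0.5] at dt = 0.05 (11 points) with σ = 0.07.  The
  desk-scale candidate set (49 reactions) lists the four
  binding/expression reactions usually treated as known biology first,
  then enumerates candidates for the mechanistically uncertain chemistry
  completely over three template classes — degradation A -> 0,
  dimerization 2A -> B, dissociation A -> 2B — so the true
  dimerization/degradation reactions sit inside full decoy classes rather
  than among hand-picked alternatives.

What the generators emulate: multiplicative, median-unbiased measurement
noise on a deterministic mass-action trajectory, on a regular grid, with
known observation maps.  What they do not: intrinsic (demographic)
stochasticity, missing data, irregular sampling, instrument-specific error
structure, or model misspecification (the truth is always inside the
library).  Passing tests therefore demonstrate recovery under the stated
noise model, not robustness to real measurement pipelines.

## Problem sizes used in the shipped analyses

The bundled analyses run at a reduced sampling budget chosen as the
smallest that gives stable medians and clean within-mode diagnostics on
these fixtures: predator-prey fits use 2 chains × (300–400 warmup +
400–500 draws); the auto-regulation exercise uses 4 chains × (600 warmup
+ 400 draws) over the 49-candidate library — the longer warmup lets
spurious reactions lifted by the warm start relax back to the shrunken
region before draws are collected.  The full-size version of the
auto-regulation experiment (hundreds of candidates, thousands of draws)
is the same code path with larger settings.

## Known limitations

* Cold starts (no warm initialization) are impractical at very small τ;
  partially observed datasets fall back to cold starts and need either a
  larger τ or a user-supplied initialization to mix well.
* Mean-field VI underestimates posterior spread (used mainly as an
  initializer; medians are reliable on the bundled fixtures).
* The derivative variant requires complete observations and a grid dense
  enough for second-order stencils.
* Deterministic rate equations only: no chemical-master-equation or
  Langevin likelihoods.
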