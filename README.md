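# crninfer

Sparse Bayesian identification of mass-action biochemical reaction
networks from noisy time-series species concentrations.

Systems biologists often face the inverse of the usual modeling workflow:
the concentrations of a handful of species have been measured over time,
and the question is *which reactions* produced those dynamics.  `crninfer`
answers it by enumerating a large candidate library of zero-, first-, and
second-order mass-action reactions among the observed species and treating
network recovery as sparse Bayesian variable selection over the unknown
rate constants.

Given the reaction-rate equations over a candidate library of D reactions

    dX/dt = S_cᵀ (k ⊙ f(X)),      f_d(X) = ∏ [reactant concentrations],

the package places a regularized horseshoe prior on the rates,

    λᵢ ~ Cauchy⁺(0,1),   λ̃ᵢ² = c²λᵢ²/(c² + τ²λᵢ²),
    kᵢ ~ Normal(0, τλ̃ᵢ) truncated to kᵢ ≥ 0,   c ~ Inv-Gamma(a, b),

and couples it to a latent-ODE observational model,

    log X̂(tⱼ) ~ Normal(log g(Z(tⱼ)), σ²),   Z(t) the ODE solution,

where the observation map g can be the identity, a subset of species, or a
weighted sum.  Posterior sampling uses a No-U-Turn sampler with exact
gradients obtained from forward ODE sensitivities; reactions are then
pruned when `P(τλ̃ᵢ < δ) > p₀` (defaults δ=1e-3, p₀=0.90), and chains
that settle into different sparse networks are reported as separate
candidate pathways with per-mode uncertainty.  A derivative-based sparse
regression baseline (non-negative mixed ℓ1/ℓ2, finite-difference
derivatives) is included for comparison; it is faster but degrades on
sparse, noisy grids, which the latent-ODE model tolerates.

## Worked example

Recover the predator-prey network from noisy observations (prey Y,
predator P; true system `Y -> 2Y` at 1.0, `P + Y -> 2P` at 0.01,
`P -> 0` at 0.3, hidden among 16 candidates):

```python
import numpy as np
from crninfer import (make_lotka_volterra_dataset, HorseshoeModelSpec,
                      HorseshoeConfig, run_mcmc, prune, PruneConfig)

system = make_lotka_volterra_dataset(dt=0.2, sigma=0.2, seed=1)
spec = HorseshoeModelSpec(
    library=system.library,
    datasets=(system.dataset,),
    config=HorseshoeConfig(tau=1e-8, slab_a=4, slab_b=4),
    nsub=2,
)
samples = run_mcmc(spec, chains=2, warmup=300, draws=500, seed=50)
net = prune(samples, PruneConfig(delta=1e-3, p0=0.90))
for i in net.retained:
    lo, hi = net.intervals[i]
    print(f"{system.library.reactions[i]}  median={net.medians[i]:.4f}  "
          f"90% CI=({lo:.4f}, {hi:.4f})")
```

Output from the run above:

```
Y -> 2 Y  median=0.9685  90% CI=(0.9523, 0.9849)
P + Y -> 2 P  median=0.0094  90% CI=(0.0092, 0.0095)
P -> 0  median=0.3067  90% CI=(0.3044, 0.3090)
```

Exactly the three generating reactions survive pruning (the other 13
candidates have effective scales τλ̃ᵢ below 1e-3 with posterior
probability 1), and the medians sit within a few percent of the true rates
(1, 0.01, 0.3) — the residual offset reflects the finite noisy sample, not
the sampler.

The same machinery runs from the shell:

```
crninfer make-library --preset lv-table1 --out library.txt
crninfer simulate --fixture lv --dt 0.2 --seed 1 --out data.csv
crninfer fit --config run.yaml --fast --out fit/
crninfer report --config run.yaml --posterior fit/posterior --out report/
crninfer baseline --config run.yaml --grid --out baseline/
```

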