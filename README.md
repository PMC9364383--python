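# coxsvb — sparse variational Bayes for high-dimensional Cox models

`coxsvb` does Bayesian variable selection, effect estimation and uncertainty
quantification for right-censored survival outcomes with many more covariates
than subjects — the situation of transcriptomic studies where a handful of
genes among thousands drive survival. It fits a proportional hazards model
with a spike-and-slab prior by mean-field variational inference, so a full
(approximate) posterior is available at a tiny fraction of the cost of MCMC.

## Model

For data `D = {(t_i, δ_i, x_i)}` (observed time, event indicator, covariates),
the hazard is `h(t; x) = h0(t) exp(βᵀx)` and inference uses Cox's partial
likelihood

    L_p(D; β) = ∏_{i: δ_i=1}  exp(βᵀx_i) / Σ_{r ∈ R(t_i)} exp(βᵀx_r),

with risk sets `R(t_i) = {r : t_r ≥ t_i}`, leaving the baseline hazard
unspecified. Each coefficient gets a spike-and-slab prior

    β_j | z_j ~ z_j Laplace(λ) + (1 − z_j) δ0,
    z_j | w_j ~ Bernoulli(w_j),    w_j ~ Beta(a0, b0),

— a Dirac spike at zero for exclusion and a Laplace slab (density
`λ/2 · e^{−λ|β|}`) that avoids the over-shrinkage of Gaussian slabs. The
posterior is approximated within the mean-field family

    Q = ⊗_j [ γ_j N(μ_j, σ_j²) + (1 − γ_j) δ0 ],

so `γ_j = Q(β_j ≠ 0)` is a posterior inclusion probability, directly usable
for variable selection. The fit minimizes a surrogate Kullback–Leibler
objective by coordinate ascent: each `μ_j` and `σ_j` solves a smooth 1-D
problem by bracketed Brent minimization and each `γ_j` is a closed-form
sigmoid update; see `docs/methods.md` for the objectives and all numerical
choices.

Posterior summaries include the posterior mean `β̂_j = γ_j μ_j`, marginal 95%
credible sets (an interval, the spike `{0}`, or their union), selection
thresholds controlling the Bayesian false discovery rate, prognostic indices
`η̂_i = β̂ᵀx_i` with Harrell's c-index, and pairwise posterior probabilities
`Q(βᵀx_i ≥ βᵀx_j)` that one patient is at greater risk than another. A
Metropolis-within-Gibbs sampler targeting the exact posterior is included as
a small-scale correctness reference, along with the synthetic-data generator
and replicate-study harness used to validate the method.

## Worked example

```python
import numpy as np
from coxsvb import (SimulationConfig, PriorSpec, simulate_dataset, fit,
                    posterior_mean, select_at_half, credible_set,
                    bayesian_fdr_threshold)

cfg = SimulationConfig(n=200, p=500, s=5, c=0.25, seed=7)   # 25% censoring
sim = simulate_dataset(cfg)
prior = PriorSpec(lam=1.0, a0=1.0, b0=float(cfg.p))
result = fit(sim.data, prior, seed=7)
params = result.params

print(f"converged in {result.n_iterations} sweeps")
print(f"true support: {sim.support.tolist()}")
print(f"selected (gamma >= 0.5): {select_at_half(params).tolist()}")
beta_hat = posterior_mean(params)
for j in sim.support:
    s = credible_set(params, j)
    print(f"  beta[{j}] true {sim.beta0[j]:+.3f}  estimate {beta_hat[j]:+.3f}  "
          f"gamma {params.gamma[j]:.3f}  95% set [{s.lower:+.3f}, {s.upper:+.3f}]")
report = bayesian_fdr_threshold(params.gamma, alpha=0.10)
print(f"Bayesian-FDR selection at alpha=0.10: {report.selected.tolist()} "
      f"(threshold {report.threshold_used:.3f}, FDR {report.bayes_fdr_at_threshold:.4f})")
```

Output:

```
converged in 17 sweeps
true support: [26, 101, 151, 396, 407]
selected (gamma >= 0.5): [26, 101, 151, 396, 407]
  beta[26] true +0.754  estimate +0.841  gamma 1.000  95% set [+0.669, +1.014]
  beta[101] true -0.632  estimate -0.809  gamma 1.000  95% set [-0.971, -0.647]
  beta[151] true +1.597  estimate +1.706  gamma 1.000  95% set [+1.545, +1.868]
  beta[396] true -0.591  estimate -0.672  gamma 1.000  95% set [-0.845, -0.499]
  beta[407] true +0.964  estimate +1.289  gamma 1.000  95% set [+1.125, +1.454]
Bayesian-FDR selection at alpha=0.10: [26, 101, 151, 396, 407] (threshold 0.023, FDR 0.0000)
```

All five causal covariates (out of 500) are recovered with inclusion
probability ≈ 1, no false selections, and credible sets close to the truth.

A command-line interface mirrors the library: `coxsvb fit`, `simulate`,
`replicate-study`, `cv` (cross-validated tuning of λ and a0), `mcmc` and
`compare-risk`; all outputs are TSV/JSON under `--out-dir`.

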