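# Methods

## Model and inference target

The package fits the proportional hazards model `h(t; x) = h0(t) exp(βᵀx)`
to right-censored data `D = {(t_i, δ_i, x_i)}` through Cox's partial
likelihood `L_p(D; β)`, which conditions on the order of the observed event
times and eliminates the baseline hazard `h0`. The posterior is proportional
to `L_p` times a spike-and-slab prior: per coefficient, a Dirac mass at zero
with prior exclusion weight and a `Laplace(λ)` slab, the inclusion
indicators `z_j` mixed over `w_j ~ Beta(a0, b0)` so the model adapts to an
unknown sparsity level. The Laplace slab is deliberate: Gaussian slabs
over-shrink large effects, while the Laplace penalty is linear in `|β|`.

Because summing over `2^p` support patterns is hopeless at transcriptomic
scale, inference is variational: the posterior is approximated by the
mean-field family `⊗_j [γ_j N(μ_j, σ_j²) + (1 − γ_j) δ0]`. This keeps the
discrete-selection structure (the `γ_j` are inclusion probabilities) with
only `O(p)` parameters. What is lost is dependence: the approximation cannot
express that two correlated covariates tend to be selected in each other's
stead, and — as with mean-field methods generally — it understates posterior
spread (visible in the credible-set calibration below).

## The coordinate-ascent updates

The exact KL divergence to the posterior is intractable because the partial
likelihood's risk-set sums sit inside a logarithm. The algorithm therefore
minimizes a surrogate bound obtained by moving the expectation inside each
risk-set sum (Jensen): `E_Q log Σ_r e^{βᵀx_r} ≤ log Σ_r E_Q e^{βᵀx_r}`, and
`E_Q e^{βᵀx_r}` factorizes coordinatewise into
`∏_k (γ_k M(x_rk, μ_k, σ_k) + 1 − γ_k)` with the slab MGF factor
`M(x, μ, σ) = exp(μx + σ²x²/2)`. Writing `P_j(x_r)` for the product over
`k ≠ j`, the per-coordinate objectives are

    f(μ_j) = Σ_{i: δ_i=1} [ log Σ_{r∈R(t_i)} M(x_rj, μ_j, σ_j) P_j(x_r) − μ_j x_ij ]
             + λ E|β_j|,
    g(σ_j) = (same risk-set term) + λ E|β_j| − log σ_j,

where `λE|β_j| = λ[σ_j √(2/π) e^{−μ_j²/(2σ_j²)} + μ_j(1 − 2Φ(−μ_j/σ_j))]` is
the expected Laplace penalty under the Normal slab (a folded-normal mean)
and `−log σ_j` is the entropy barrier that keeps the slab from collapsing.
The inclusion update is closed form, `γ_j = sigmoid(ζ_j)` with

    ζ_j = log(a0/b0) − λE|β_j| − Δ_j + log(λ σ_j √(2π) / 2) + 1/2,

where `Δ_j` is the likelihood cost of inclusion (the risk-set term with `M`
minus the same term without it, minus `μ_j Σ x_ij`), and the remaining terms
are the expected log slab density plus the Normal entropy. The prior log-odds
use `log(a0/b0)`, the Beta prior collapsed to its odds.

One sweep visits coordinates `j = 1..p` in ascending order, updating `μ_j`,
then `σ_j`, then `γ_j` — a fixed order chosen for reproducibility. The
stopping rule is the total absolute parameter change per sweep falling below
`tol` (default `1e-3`; the change trajectory is recorded in the fit result
and is exactly what the rule consumes). The evidence lower bound is *not*
used for stopping — it has no closed form here and is only available by
Monte Carlo — but `elbo_mc` evaluates it for tuning and diagnostics.

## Numerical choices

* **Log space throughout.** `μ_j x + σ_j² x²/2` can exceed the double range
  for expression-scale covariates, so `M` is never exponentiated raw. Each
  factor `log(γM + 1 − γ)` is a `logaddexp`; risk-set sums become prefix
  logsumexps after sorting subjects by decreasing time (risk sets are then
  prefixes, ties sharing a prefix end). A sweep is `O(np)` thanks to a cached
  `n × p` matrix of log factors with per-row sums: `log P_j` is the row sum
  minus column `j`, only column `j` is refreshed after its update, and the
  row sums are rebuilt once per sweep to stop drift (consistency is checked
  at `1e-10`).
* **1-D minimization.** `μ_j` and `σ_j` have no closed-form minimizers; both
  use bounded Brent (golden section + parabolic interpolation, `xatol 1e-6`),
  `μ_j` on a width-10 bracket centered at the current value and `σ_j` on the
  log scale within `[1e-4, 10]`, starting from a ±1.5 log-window around the
  current value; brackets expand on boundary hits (up to 3 times). The inner
  objective and the Brent loop are numba-compiled — the objective costs one
  exp per subject via a running-max logsumexp — which is what makes a
  `(n, p) = (200, 1000)` fit take seconds. An update that fails to lower its
  own objective (possible only through floating-point rounding at the
  optimum) keeps the previous value, so per-coordinate descent holds exactly.
* **Clamping.** `γ_j` is clipped to `[1e-12, 1 − 1e-12]` after the sigmoid so
  all log factors stay finite.
* **Initialization.** `μ` starts at an l1-penalized Cox fit (coordinate-descent
  elastic net with pure l1 penalty), taking the smallest penalty on a short
  path that keeps at most `min(n/2, 200)` coefficients nonzero — the slab
  means play the role of *unshrunk* effect sizes, so the penalty should be
  light; if the l1 fit fails, `μ = 0` with a warning. `γ` starts at 0.5
  (indifference) and `σ` at 0.05, to which the method is insensitive. The
  surrogate objective is non-convex, so coordinate ascent only finds a local
  optimum and a sensible start matters mainly for `μ` and `γ`.

## Posterior summaries

* **Point estimate and selection.** `β̂_j = γ_j μ_j`; default selection is
  `γ_j ≥ 0.5`.
* **Credible sets.** The 95% marginal set is `I_j` when `γ_j > 0.95`, the
  spike `{0}` when `γ_j < 0.05`, and `I_j ∪ {0}` otherwise, with `I_j`
  symmetric about `μ_j` (for a Normal slab the smallest interval) and sized
  so the *total* variational mass of the set — slab mass times `γ_j`, plus
  the spike atom whenever `0` lies in the set — reaches the level: in the
  union case the slab must contribute `(0.95 − (1 − γ_j))/γ_j`. This makes
  "the set holds 95% of the posterior mass" literally true, verified by
  numerical integration in the tests.
* **Bayesian FDR.** The selected-set FDR at threshold `k` is
  `Σ_j (1 − γ_j) 1{γ_j > k} / Σ_j 1{γ_j > k}`. The reported threshold is the
  *least stringent* one controlling FDR below `α` (candidates sit just below
  each distinct `γ` value): larger thresholds trivially satisfy the bound
  with fewer discoveries, and the ratio is undefined for an empty set, so
  the largest admissible selected set is the useful operating point. When no
  nonempty set qualifies, an empty flagged selection is returned.
* **ELBO.** `E_Q[log L_p]` by Monte Carlo (default 10⁴ draws, seeded) minus a
  closed-form `KL(Q ‖ prior)`: per coordinate a Bernoulli KL against the
  prior inclusion probability plus `γ_j · KL(N(μ_j, σ_j²) ‖ Laplace(λ))`,
  the latter assembled from the folded-normal mean, `log(λ/2)` and the
  Normal entropy. By default the Beta-Bernoulli prior is collapsed to its
  marginal inclusion probability `a0/(a0+b0)`; an exact variant
  (`variant="beta"`) evaluates the exchangeable model-size marginal through
  the Poisson-binomial law of `Σ z_j` — the difference is negligible at
  `b0 = p` scale but both are exposed.
* **Risk comparison.** `Q(βᵀx_i ≥ βᵀx_j)` by Monte Carlo over posterior
  draws (10⁴ by default, seeded); the matrix version shares one draw set
  across all pairs, so `P(i,j) + P(j,i) ≥ 1` holds exactly (ties at the
  spike count on both sides). Harrell's c-index of the prognostic index is
  computed by exact pair enumeration with half-credit ties.

## Reference MCMC sampler

For small problems a Metropolis-within-Gibbs chain targets the *exact*
posterior, as the correctness oracle: the Beta weight is marginalized
analytically (model-size prior `B(a0+k, b0+p−k)/B(a0, b0)`), and each sweep
proposes an add/delete flip per coordinate (entering coefficients drawn from
the `Laplace(λ)` slab, whose density then cancels in the acceptance ratio)
plus a random-walk move for included coefficients, with per-coordinate
scales adapted toward ≈0.3 acceptance during burn-in and frozen after.
Defaults are 10,000 iterations with 1,000 burn-in. Any correct sampler
targets the same posterior, which is all the oracle role requires; this one
makes no efficiency claims and warns above `p = 2000`. Tests verify it
against brute-force model enumeration with slab quadrature at `p ≤ 2` and
against the prior marginal `a0/(a0+b0)` in a likelihood-free run.

## Synthetic data and the replicate harness

The generator emulates a standard high-dimensional survival benchmark:
event times drawn with unit baseline hazard — i.e. `T | x` exponential with
rate `e^{β0ᵀx}` — so `T e^{β0ᵀx} ~ Exp(1)` gives a distribution-free check;
censoring by uniform subsampling (each subject censored with probability
`c`, its time replaced by `U(0, t)`); `s` causal coefficients at uniform
magnitudes in `[0.5, 2.0]` with random signs and uniformly chosen indices.
Designs: independent `N(0, I)`; block-equicorrelated (blocks of 50 at
correlation 0.6, both configurable); or a user-parameterized multivariate
normal standing in for moments estimated from a real expression matrix, with
causal indices restricted to features of variance ≥ 1. Each replicate spawns
four independent RNG streams (coefficients, design, survival, censoring)
from one seed, and replicate `k` of a study uses `base_seed + k`, making
whole studies bit-reproducible. What the generator does *not* emulate:
heavy-tailed or count-valued expression scales, non-proportional hazards,
informative censoring, and gene-network correlation structure — so passing
studies demonstrate correctness of the machinery under the stated model, not
robustness to those violations.

The harness reports, across replicates, median and (5%, 95%) quantiles of
the ℓ2/ℓ1 errors of `β̂`, TPR/FDR of selection at `γ ≥ 0.5` (an empty
selection has FDR 0), and the AUC of `γ` as a ranking score (midrank ties),
plus mean/sd of credible-set coverage and Lebesgue size split by zero versus
nonzero truth. Replicate failures are recorded and excluded with a count,
never silently. At the benchmark configuration `(n, p, s) = (200, 1000, 10)`
the studies here use 20–30 replicates (the per-replicate metrics are stable
enough that medians move little beyond that), and the observed behavior
matches the method's profile: essentially perfect selection, ℓ2 error ≈
0.3–0.4, zero-coefficient credible sets equal to `{0}` (coverage 1, size 0),
and nonzero-coefficient coverage around 0.8 at size ≈ 0.32 — below the
nominal 95% because mean-field approximations underestimate posterior
variance.

## Hyperparameters

| parameter | meaning | default / guidance |
|---|---|---|
| `λ` | Laplace slab rate; larger ⇒ more shrinkage of included effects | 1.0; 0.5–2.0 sensible, tunable by CV over a grid |
| `a0, b0` | Beta prior on inclusion weight; `a0/(a0+b0)` ≈ expected sparsity | benchmark profile `a0=1, b0=p`; omics profile `a0=p/100, b0=p` |
| `tol` | stopping threshold on total absolute parameter change | 1e-3 |
| `max_iter` | sweep cap | 1000 |
| MC draws | ELL/ELBO and risk-comparison estimates | 10⁴, always seeded |

Cross-validation (`tuning.cv_grid_search`) scores each `(λ, a0)` cell on
training and validation folds by Monte-Carlo ELBO, expected log partial
likelihood, and c-index; fold centering statistics come from training folds
only. No single criterion dominates in practice, so all three are always
reported; the default selector is validation ELL, with ties broken toward
larger `λ` (the sparser model).

## Known limitations

* Mean-field independence: no joint-selection statements across correlated
  covariates; credible sets for true effects under-cover (≈0.8 at nominal
  0.95 in the benchmark study) while zero coefficients are handled perfectly.
* The surrogate bound's minimizer is not the exact KL minimizer; agreement
  with the exact posterior (via the MCMC oracle) is excellent for posterior
  means and decided inclusion probabilities, which is what the method is for.
* Coordinate ascent on a non-convex objective: results can depend on
  initialization; the l1 start makes runs reproducible and empirically
  robust.
* No Efron-style tie correction: risk sets use the literal `t_r ≥ t_i`
  definition, appropriate for continuous survival times where ties are rare.
* Out of scope by design: baseline-hazard estimation and survival-function
  prediction, left truncation, competing risks, time-varying covariates.
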