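"""Reference posterior sampler for the exact spike-and-slab Cox posterior.

Metropolis-within-Gibbs on (beta, z) targeting

    pi(beta, z | D) proportional to L_p(D; beta_z) *
        prod_{j: z_j=1} (lam/2) exp(-lam |beta_j|) * m(|z|),

where the Beta(a0, b0) mixing weight is marginalized analytically,
m(k) = B(a0 + k, b0 + p - k) / B(a0, b0).  Moves per coordinate and sweep:

* add/delete flip of z_j with a Laplace(lam) proposal for the entering
  coefficient (the proposal cancels the slab density, leaving the
  likelihood ratio times m(k +/- 1)/m(k)),
* a random-walk update of beta_j when z_j = 1, with per-coordinate scales
  adapted toward ~0.3 acceptance during burn-in and frozen afterwards.

Any correct sampler targets the same posterior; this one plays the role of
a slow, asymptotically exact oracle against which the variational
approximation is compared at small scale.  It is not intended to compete
on speed and warns above p = 2000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .cavi import PriorSpec
from .data import SurvivalDataset
from .inference import CredibleSet
from .likelihood import RiskPrefix

logger = logging.getLogger("coxsvb")

__all__ = ["McmcChain", "McmcSummary", "run_mcmc", "chain_summaries"]


@dataclass
class McmcChain:
    """Post-warmup included draws of (beta, z) plus run metadata.

    ``beta`` is (n_kept, p) with beta_j = 0 whenever z_j = 0.
    """

    beta: np.ndarray
    z: np.ndarray
    burn_in: int
    seed: int
    accept_rates: dict[str, float]
    rw_scales: np.ndarray

    @property
    def n_kept(self) -> int:
        return self.beta.shape[0]


@dataclass
class McmcSummary:
    mean: np.ndarray
    mean_se: np.ndarray          # batch-means Monte-Carlo error of the mean
    sd: np.ndarray               # posterior standard deviation per coordinate
    inclusion: np.ndarray
    credible_sets: list[CredibleSet]


class _PartialLikelihood:
    """Incremental partial-likelihood evaluation under coordinate moves."""

    def __init__(self, data: SurvivalDataset):
        self.prefix = RiskPrefix.from_dataset(data)
        self.X = self.prefix.design_sorted
        self.x_event_sum = self.prefix.event_design.sum(axis=0)
        self.eta = np.zeros(self.X.shape[0])
        self.eta_event = 0.0
        self.value = self._value(self.eta, self.eta_event)

    def _value(self, eta: np.ndarray, eta_event: float) -> float:
        return float(eta_event - self.prefix.event_logsumexp(eta))

    def propose(self, j: int, delta: float) -> tuple[float, np.ndarray, float]:
        eta_new = self.eta + delta * self.X[:, j]
        eta_event_new = self.eta_event + delta * self.x_event_sum[j]
        return self._value(eta_new, eta_event_new), eta_new, eta_event_new

    def accept(self, value: float, eta: np.ndarray, eta_event: float) -> None:
        self.value, self.eta, self.eta_event = value, eta, eta_event


def run_mcmc(
    data: SurvivalDataset | None,
    prior: PriorSpec,
    p: int | None = None,
    n_iter: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
    rw_scale: float = 0.5,
    target_accept: float = 0.3,
) -> McmcChain:
    """Sample the spike-and-slab Cox posterior; reproducible given seed.

    With ``data=None`` (and ``p`` given) the likelihood is identically 1
    and the chain targets the prior — useful as an analytic sanity check,
    since the marginal inclusion probability is then a0/(a0+b0).
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if data is not None:
        p = data.p
        lik = _PartialLikelihood(data)
    elif p is None:
        raise ValueError("p is required for a prior-only run")
    else:
        lik = None
    if p > 2000:
        logger.warning("MCMC at p=%d will be slow; intended for small p", p)
    rng = np.random.default_rng(seed)
    lam, a0, b0 = prior.lam, prior.a0, prior.b0
    # log m(k) for model sizes 0..p (Beta-Bernoulli marginal, w integrated out)
    k = np.arange(p + 1)
    log_m = special.betaln(a0 + k, b0 + p - k) - special.betaln(a0, b0)

    beta = np.zeros(p)
    z = np.zeros(p, dtype=bool)
    size = 0
    scales = np.full(p, rw_scale)
    flip_prop = flip_acc = rw_prop = rw_acc = 0
    rw_acc_recent = np.zeros(p)
    rw_prop_recent = np.zeros(p)

    kept_beta = np.empty((n_iter - burn_in, p))
    kept_z = np.empty((n_iter - burn_in, p), dtype=bool)

    for it in range(n_iter):
        for j in range(p):
            # --- add/delete flip ---
            flip_prop += 1
            if not z[j]:
                b_new = rng.laplace(0.0, 1.0 / lam)
                log_alpha = log_m[size + 1] - log_m[size]
                if lik is not None:
                    val, eta, eta_ev = lik.propose(j, b_new)
                    log_alpha += val - lik.value
                if np.log(rng.random()) < log_alpha:
                    flip_acc += 1
                    z[j] = True
                    beta[j] = b_new
                    size += 1
                    if lik is not None:
                        lik.accept(val, eta, eta_ev)
            else:
                log_alpha = log_m[size - 1] - log_m[size]
                if lik is not None:
                    val, eta, eta_ev = lik.propose(j, -beta[j])
                    log_alpha += val - lik.value
                if np.log(rng.random()) < log_alpha:
                    flip_acc += 1
                    z[j] = False
                    beta[j] = 0.0
                    size -= 1
                    if lik is not None:
                        lik.accept(val, eta, eta_ev)
            # --- random walk on included coefficients ---
            if z[j]:
                rw_prop += 1
                rw_prop_recent[j] += 1
                b_new = beta[j] + scales[j] * rng.standard_normal()
                log_alpha = -lam * (abs(b_new) - abs(beta[j]))
                if lik is not None:
                    val, eta, eta_ev = lik.propose(j, b_new - beta[j])
                    log_alpha += val - lik.value
                if np.log(rng.random()) < log_alpha:
                    rw_acc += 1
                    rw_acc_recent[j] += 1
                    beta[j] = b_new
                    if lik is not None:
                        lik.accept(val, eta, eta_ev)
        # adapt random-walk scales toward the target acceptance during burn-in
        if it < burn_in and (it + 1) % 50 == 0:
            tried = rw_prop_recent > 0
            rate = np.divide(rw_acc_recent, rw_prop_recent, where=tried,
                             out=np.full(p, target_accept))
            scales[tried] *= np.exp((rate[tried] - target_accept))
            scales = np.clip(scales, 1e-3, 10.0)
            rw_acc_recent[:] = 0.0
            rw_prop_recent[:] = 0.0
        if it >= burn_in:
            kept_beta[it - burn_in] = beta
            kept_z[it - burn_in] = z

    return McmcChain(
        beta=kept_beta,
        z=kept_z,
        burn_in=burn_in,
        seed=seed,
        accept_rates={
            "flip": flip_acc / max(flip_prop, 1),
            "rw": rw_acc / max(rw_prop, 1),
        },
        rw_scales=scales,
    )


def chain_summaries(chain: McmcChain, level: float = 0.95) -> McmcSummary:
    """Posterior means, inclusion probabilities and marginal credible sets.

    Credible sets follow the same three-case rule as the variational
    summaries, with I_j taken as the central empirical interval of the
    slab draws (draws with z_j = 1) holding the required mass.
    """
    mean = chain.beta.mean(axis=0)
    inclusion = chain.z.mean(axis=0)
    mean_se = _batch_means_se(chain.beta)
    sets: list[CredibleSet] = []
    for j in range(chain.beta.shape[1]):
        g = inclusion[j]
        if g < 1.0 - level:
            sets.append(CredibleSet("spike_only", 0.0, 0.0, level, 0.0))
            continue
        slab = chain.beta[chain.z[:, j], j]
        if g > level:
            kind, mass = "interval", level / g
        else:
            kind, mass = "interval_plus_spike", (level - (1.0 - g)) / g
        mass = min(max(mass, 0.0), 1.0)
        lo, hi = np.quantile(slab, [0.5 - mass / 2.0, 0.5 + mass / 2.0])
        sets.append(CredibleSet(kind, float(lo), float(hi), level, float(hi - lo)))
    return McmcSummary(mean=mean, mean_se=mean_se,
                       sd=chain.beta.std(axis=0, ddof=1),
                       inclusion=inclusion, credible_sets=sets)


def _batch_means_se(draws: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Batch-means Monte-Carlo SE of the posterior mean, per coordinate."""
    n = draws.shape[0]
    usable = n - n % n_batches
    batches = draws[:usable].reshape(n_batches, usable // n_batches, -1).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
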