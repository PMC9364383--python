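"""Posterior summarization for the spike-and-slab variational posterior.

Point estimates (posterior mean gamma_j mu_j), selection at inclusion
probability 0.5, marginal credible sets via the three-case rule, selection
thresholds controlling the Bayesian false discovery rate, the Monte-Carlo
ELBO, prognostic indices, Harrell's concordance, and pairwise
risk-comparison probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .cavi import PriorSpec, VariationalParams
from .data import RiskSetIndex, SurvivalDataset
from .likelihood import expected_log_partial_likelihood_mc, laplace_slab_expectation

logger = logging.getLogger("coxsvb")

__all__ = [
    "CredibleSet",
    "SelectionReport",
    "posterior_mean",
    "select_at_half",
    "credible_set",
    "credible_sets",
    "coverage_and_size",
    "bayesian_fdr_threshold",
    "kl_q_prior",
    "elbo_mc",
    "prognostic_index",
    "concordance_index",
    "risk_comparison_prob",
    "risk_comparison_matrix",
]


def posterior_mean(params: VariationalParams) -> np.ndarray:
    """Posterior mean coefficients: beta_hat_j = gamma_j mu_j."""
    return params.gamma * params.mu


def select_at_half(params: VariationalParams) -> np.ndarray:
    """Indices with inclusion probability gamma_j >= 0.5 (inclusive)."""
    return np.flatnonzero(params.gamma >= 0.5)


@dataclass(frozen=True)
class CredibleSet:
    """A marginal credible set: an interval, the spike {0}, or their union.

    ``lebesgue_size`` is upper - lower for the interval component and 0 for
    a pure spike; the spike atom adds no Lebesgue measure.
    """

    kind: str                      # "interval" | "spike_only" | "interval_plus_spike"
    lower: float
    upper: float
    mass_level: float
    lebesgue_size: float

    def contains(self, value: float) -> bool:
        if self.kind == "spike_only":
            return value == 0.0
        in_interval = self.lower <= value <= self.upper
        if self.kind == "interval_plus_spike":
            return in_interval or value == 0.0
        return in_interval


def credible_set(
    params: VariationalParams, j: int, level: float = 0.95
) -> CredibleSet:
    """Marginal credible set S_j for coefficient j at the given level.

    Three-case rule: S_j = I_j when gamma_j > level; S_j = {0} when
    gamma_j < 1 - level; otherwise S_j = I_j union {0}.  I_j is the
    smallest interval of the Normal slab (symmetric about mu_j) such that
    the total variational mass of S_j — gamma_j times the slab mass of I_j,
    plus (1 - gamma_j) when 0 is in S_j — reaches the level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    g = float(params.gamma[j])
    mu = float(params.mu[j])
    sigma = float(params.sigma[j])
    if g < 1.0 - level:
        return CredibleSet("spike_only", 0.0, 0.0, level, 0.0)
    if g > level:
        kind = "interval"
        slab_mass = level / g
    else:
        kind = "interval_plus_spike"
        slab_mass = (level - (1.0 - g)) / g  # spike atom covers (1 - g)
    slab_mass = min(max(slab_mass, 0.0), 1.0 - 1e-15)
    z = stats.norm.ppf(0.5 * (1.0 + slab_mass))
    lower, upper = mu - z * sigma, mu + z * sigma
    return CredibleSet(kind, lower, upper, level, upper - lower)


def credible_sets(params: VariationalParams, level: float = 0.95) -> list[CredibleSet]:
    return [credible_set(params, j, level) for j in range(params.p)]


def coverage_and_size(
    sets: list[CredibleSet], truth: np.ndarray
) -> dict[str, float]:
    """Mean coverage and Lebesgue size, split by zero/nonzero truth."""
    truth = np.asarray(truth, dtype=float)
    if len(sets) != truth.shape[0]:
        raise ValueError("one credible set required per coefficient")
    covered = np.array([s.contains(b) for s, b in zip(sets, truth)], dtype=float)
    size = np.array([s.lebesgue_size for s in sets], dtype=float)
    nz = truth != 0
    out: dict[str, float] = {}
    out["coverage_nonzero"] = float(covered[nz].mean()) if nz.any() else float("nan")
    out["size_nonzero"] = float(size[nz].mean()) if nz.any() else float("nan")
    out["coverage_zero"] = float(covered[~nz].mean()) if (~nz).any() else float("nan")
    out["size_zero"] = float(size[~nz].mean()) if (~nz).any() else float("nan")
    return out


@dataclass
class SelectionReport:
    selected: np.ndarray
    threshold_used: float
    inclusion_probs: np.ndarray
    bayes_fdr_at_threshold: float
    qualifying: bool  # False when no threshold controls the FDR


def bayesian_fdr_threshold(gamma: np.ndarray, alpha: float) -> SelectionReport:
    """Least stringent inclusion threshold whose Bayesian FDR is below alpha.

    The Bayesian FDR of the set {j : gamma_j > k} is
    sum_j (1 - gamma_j) 1{gamma_j > k} / sum_j 1{gamma_j > k}.  Candidate
    thresholds are the distinct gamma values; among those whose selected
    set satisfies FDR < alpha the smallest k (largest selected set) is
    returned, since any larger k trivially satisfies the bound with fewer
    discoveries.  When no nonempty set qualifies, an empty selection is
    returned with ``qualifying`` False.
    """
    gamma = np.asarray(gamma, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if np.any(gamma < 0) or np.any(gamma > 1):
        raise ValueError("gamma must lie in [0, 1]")
    best_k: float | None = None
    best_fdr = float("nan")
    vals = np.unique(gamma)
    # achievable sets are {gamma >= v} for each distinct v > 0, realized by
    # the threshold just below v (the next lower distinct value, or 0)
    for i, v in enumerate(vals):
        if v == 0.0:
            continue
        k = float(vals[i - 1]) if i > 0 else 0.0
        sel = gamma > k
        if not sel.any():
            continue
        fdr = float((1.0 - gamma[sel]).sum() / sel.sum())
        if fdr < alpha:
            best_k, best_fdr = k, fdr
            break  # ascending scan: first admissible k is the least stringent
    if best_k is None:
        logger.info("no threshold controls the Bayesian FDR at alpha=%.3g", alpha)
        return SelectionReport(
            selected=np.array([], dtype=np.intp),
            threshold_used=float(gamma.max(initial=1.0)),
            inclusion_probs=gamma,
            bayes_fdr_at_threshold=0.0,
            qualifying=False,
        )
    return SelectionReport(
        selected=np.flatnonzero(gamma > best_k),
        threshold_used=best_k,
        inclusion_probs=gamma,
        bayes_fdr_at_threshold=best_fdr,
        qualifying=True,
    )


def kl_q_prior(
    params: VariationalParams, prior: PriorSpec, variant: str = "collapsed"
) -> float:
    """KL divergence between the variational posterior and the prior.

    Per coordinate: a Bernoulli term between gamma_j and the prior
    inclusion probability, plus gamma_j times KL(N(mu_j, sigma_j^2) ||
    Laplace(lam)) = lam E|beta_j| - log(lam/2) - log(sqrt(2 pi) sigma_j) - 1/2.

    ``variant="collapsed"`` (default) collapses the Beta-Bernoulli prior to
    its marginal inclusion probability a0/(a0+b0).  ``variant="beta"``
    evaluates the exchangeable Beta-Bernoulli marginal over the model size
    exactly (Poisson-binomial expectation of log Beta functions).
    """
    g = np.clip(params.gamma, 1e-300, 1.0)
    one_m = np.clip(1.0 - params.gamma, 1e-300, 1.0)
    slab_kl = (
        laplace_slab_expectation(params.mu, params.sigma, prior.lam)
        - np.log(prior.lam / 2.0)
        - np.log(np.sqrt(2.0 * np.pi) * params.sigma)
        - 0.5
    )
    entropy_terms = float(np.sum(g * np.log(g) + one_m * np.log(one_m)))
    slab_total = float(np.sum(params.gamma * slab_kl))
    if variant == "collapsed":
        w = prior.a0 / (prior.a0 + prior.b0)
        cross = float(
            np.sum(params.gamma * np.log(w) + (1.0 - params.gamma) * np.log(1.0 - w))
        )
        return entropy_terms + slab_total - cross
    if variant == "beta":
        # E_Q[log prior(z)] with prior(z) = B(a0+|z|, b0+p-|z|) / B(a0, b0)
        p = params.p
        pmf = _poisson_binomial_pmf(params.gamma)
        k = np.arange(p + 1)
        log_prior_size = (
            special.betaln(prior.a0 + k, prior.b0 + p - k)
            - special.betaln(prior.a0, prior.b0)
        )
        return entropy_terms + slab_total - float(pmf @ log_prior_size)
    raise ValueError(f"unknown KL variant {variant!r}")


def _poisson_binomial_pmf(gamma: np.ndarray) -> np.ndarray:
    """Distribution of sum of independent Bernoulli(gamma_j) by convolution."""
    pmf = np.array([1.0])
    for g in gamma:
        pmf = np.convolve(pmf, [1.0 - g, g])
    return pmf


def elbo_mc(
    data: SurvivalDataset,
    risk: RiskSetIndex | None,
    params: VariationalParams,
    prior: PriorSpec,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    kl_variant: str = "collapsed",
) -> tuple[float, float]:
    """ELBO = E_Q[log L_p] - KL(Q || prior), with Monte-Carlo standard error.

    The expected log partial likelihood is estimated by Monte Carlo; the KL
    term is closed form, so the reported SE is that of the ELL term.
    """
    ell, se = expected_log_partial_likelihood_mc(data, risk, params, n_draws, seed)
    return ell - kl_q_prior(params, prior, variant=kl_variant), se


def prognostic_index(data: SurvivalDataset, beta_hat: np.ndarray) -> np.ndarray:
    """Linear predictor eta_i = beta_hat . x_i per subject."""
    return data.design @ np.asarray(beta_hat, dtype=float)


def concordance_index(
    times: np.ndarray, events: np.ndarray, eta: np.ndarray
) -> float:
    """Harrell's c-index of risk scores eta against right-censored times.

    Usable pairs are those where the shorter observed time ends in an
    event; concordant pairs rank the earlier failure with the higher risk
    score, ties in eta count one half.  Raises if no pair is usable.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    eta = np.asarray(eta, dtype=float)
    # pair (i, j) usable iff t_i < t_j and delta_i = 1 (earlier time has event)
    t_i = times[:, None]
    usable = (t_i < times[None, :]) & (events[:, None] == 1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no comparable pairs: c-index undefined")
    e_i = eta[:, None]
    concordant = usable & (e_i > eta[None, :])
    tied = usable & (e_i == eta[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def _draw_betas(
    params: VariationalParams, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    z = rng.random((n_draws, params.p)) < params.gamma
    return np.where(
        z, params.mu + params.sigma * rng.standard_normal((n_draws, params.p)), 0.0
    )


def risk_comparison_prob(
    params: VariationalParams,
    x_i: np.ndarray,
    x_j: np.ndarray,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Posterior probability that subject i is at greater risk than j.

    Monte-Carlo estimate of Q(beta . x_i >= beta . x_j) under the
    variational posterior.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    beta = _draw_betas(params, n_draws, rng)
    return float(np.mean(beta @ d >= 0.0))


def risk_comparison_matrix(
    params: VariationalParams,
    X: np.ndarray,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Matrix of Q(beta . x_i >= beta . x_j) over rows of X (one draw set)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = _draw_betas(params, n_draws, rng)
    eta = beta @ np.asarray(X, dtype=float).T        # (n_draws, m)
    return (eta[:, :, None] >= eta[:, None, :]).mean(axis=0)
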