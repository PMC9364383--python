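"""Cox partial likelihood and variational expectation building blocks.

Everything here works in log space.  The key quantities are

* the log partial likelihood  sum_{i: delta_i=1} [ eta_i - log sum_{r in
  R(t_i)} exp(eta_r) ]  with eta = X beta,
* the per-coordinate moment factor  M(x, mu, sigma) = exp(mu x + sigma^2
  x^2 / 2)  (the MGF of the Normal slab evaluated at a covariate value),
* the excluded product  P_j(x_r) = prod_{k != j} (gamma_k M(x_rk, mu_k,
  sigma_k) + 1 - gamma_k),  maintained incrementally in a log-factor cache,
* the Laplace-slab penalty  lambda * E|beta_j|  for beta_j ~ N(mu, sigma^2).

M is never exponentiated in raw form: mu x + sigma^2 x^2 / 2 can exceed the
double-precision range for expression-scale covariates, and all the ratios
the method needs are scale-free, so sums over risk sets use shifted
logsumexp throughout.  Risk sets become prefixes of the subjects sorted by
decreasing time, so each sum over all risk sets is a single O(n) running
logsumexp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import special

from .data import RiskSetIndex, SurvivalDataset

logger = logging.getLogger("coxsvb")

GAMMA_CLAMP = 1e-12  # keeps log(gamma) and log(1 - gamma) finite

__all__ = [
    "RiskPrefix",
    "LogFactorCache",
    "log_partial_likelihood",
    "partial_likelihood_score",
    "log_mgf_term",
    "laplace_slab_expectation",
    "expected_log_partial_likelihood_mc",
    "GAMMA_CLAMP",
]


@njit(cache=True)
def _affine_event_lse(mu, half_sig2, x, x2, logp, ends_sorted):  # pragma: no cover
    """sum over events of running logsumexp of mu*x + half_sig2*x^2 + logp
    up to each (ascending) prefix end.

    Maintains a running maximum and a rescaled running sum, so each element
    costs one exp; the log is only taken at event positions.
    """
    total = 0.0
    run_max = -np.inf
    s = 0.0
    e = 0
    m = ends_sorted.shape[0]
    for r in range(x.shape[0]):
        a = mu * x[r] + half_sig2 * x2[r] + logp[r]
        if a <= run_max:
            s += np.exp(a - run_max)
        else:
            s = s * np.exp(run_max - a) + 1.0
            run_max = a
        while e < m and ends_sorted[e] == r + 1:
            total += run_max + np.log(s)
            e += 1
    return total


@njit(cache=True)
def _plain_event_lse(a, ends_sorted):  # pragma: no cover
    total = 0.0
    run_max = -np.inf
    s = 0.0
    e = 0
    m = ends_sorted.shape[0]
    for r in range(a.shape[0]):
        v = a[r]
        if v <= run_max:
            s += np.exp(v - run_max)
        else:
            s = s * np.exp(run_max - v) + 1.0
            run_max = v
        while e < m and ends_sorted[e] == r + 1:
            total += run_max + np.log(s)
            e += 1
    return total


@dataclass
class RiskPrefix:
    """Subjects sorted by decreasing time, so every risk set is a prefix.

    ``ends[k]`` is the number of sorted subjects with t_r >= t of the k-th
    event subject (events enumerated in input-row order, matching
    :class:`~coxsvb.data.RiskSetIndex.event_order`); ties share the same
    prefix end, so tied events have identical risk sets.
    """

    order: np.ndarray            # sorted position -> input row
    design_sorted: np.ndarray    # (n, p) design rows in sorted order
    ends: np.ndarray             # (n_events,) prefix length per event
    ends_sorted: np.ndarray      # ends in ascending order (for one-pass sums)
    event_rows: np.ndarray       # input-row indices of events
    event_design: np.ndarray     # (n_events, p) covariates of event subjects

    @classmethod
    def from_dataset(cls, data: SurvivalDataset) -> "RiskPrefix":
        order = np.argsort(-data.times, kind="stable")
        t_sorted = data.times[order]
        event_rows = np.flatnonzero(data.events == 1)
        if event_rows.size == 0:
            raise ValueError("no events")
        # number of subjects with t_r >= t_i == position after the last
        # sorted time >= t_i (times sorted descending -> search on negated)
        ends = np.searchsorted(-t_sorted, -data.times[event_rows], side="right")
        return cls(
            order=order,
            design_sorted=np.ascontiguousarray(data.design[order]),
            ends=ends,
            ends_sorted=np.sort(ends),
            event_rows=event_rows,
            event_design=data.design[event_rows],
        )

    def event_logsumexp(self, a: np.ndarray) -> float | np.ndarray:
        """sum over events of logsumexp of ``a`` over that event's risk set.

        ``a`` holds one value per subject in sorted order (or a stack of
        such vectors along the last axis: shape (..., n)).
        """
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            return _plain_event_lse(a, self.ends_sorted)
        lse = np.logaddexp.accumulate(a, axis=-1)
        return lse[..., self.ends - 1].sum(axis=-1)

    def affine_event_logsumexp(
        self, mu: float, half_sig2: float, x: np.ndarray, x2: np.ndarray,
        logp: np.ndarray,
    ) -> float:
        """event_logsumexp of mu*x + half_sig2*x^2 + logp in one fused pass."""
        return _affine_event_lse(mu, half_sig2, x, x2, logp, self.ends_sorted)


def log_partial_likelihood(
    data: SurvivalDataset, risk: RiskSetIndex, beta: np.ndarray
) -> float:
    """Log of Cox's partial likelihood at coefficient vector ``beta``."""
    beta = np.asarray(beta, dtype=float)
    eta = data.design @ beta
    total = 0.0
    for i, members in zip(risk.event_order, risk.risk_members):
        total += eta[i] - special.logsumexp(eta[members])
    return float(total)


def partial_likelihood_score(
    data: SurvivalDataset, risk: RiskSetIndex, beta: np.ndarray
) -> np.ndarray:
    """Gradient of the log partial likelihood.

    sum over events of [ x_i - sum_{r in R(t_i)} w_r x_r ] with softmax
    weights w over the risk set.  Not needed by the coordinate-ascent
    updates; provided to validate the likelihood implementation.
    """
    beta = np.asarray(beta, dtype=float)
    eta = data.design @ beta
    score = np.zeros(data.p)
    for i, members in zip(risk.event_order, risk.risk_members):
        w = special.softmax(eta[members])
        score += data.design[i] - w @ data.design[members]
    return score


def log_mgf_term(x, mu, sigma):
    """log M(x, mu, sigma) = mu x + sigma^2 x^2 / 2 (slab MGF exponent)."""
    x = np.asarray(x, dtype=float)
    return mu * x + 0.5 * sigma**2 * x**2


def laplace_slab_expectation(mu, sigma, lam):
    """lambda * E|beta| for beta ~ N(mu, sigma^2) (folded-normal mean).

    lambda [ sigma sqrt(2/pi) exp(-mu^2/(2 sigma^2)) + mu (1 - 2 Phi(-mu/sigma)) ].
    Symmetric in mu, always >= lambda |mu| with equality as sigma -> 0.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z = np.divide(mu, sigma, out=np.zeros_like(mu + sigma), where=sigma > 0)
    folded = sigma * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * z**2) + mu * special.erf(
        z / np.sqrt(2.0)
    )
    out = lam * np.where(sigma > 0, folded, np.abs(mu))
    return float(out) if out.ndim == 0 else out


class LogFactorCache:
    """Cache of log(gamma_k M(x_rk) + 1 - gamma_k) with row products.

    ``log_factor`` is (n, p); ``log_row_product`` is the per-row sum over
    k.  ``log_excluded(j)`` returns log P_j for every subject as the row
    product minus column j, an O(n) lookup instead of an O(np) product.
    After a coordinate update only that column and the row products are
    refreshed; a full rebuild each sweep guards against drift.
    """

    def __init__(self, design: np.ndarray, mu, sigma, gamma):
        self.design = design
        self.log_factor = np.empty_like(design)
        for j in range(design.shape[1]):
            self.log_factor[:, j] = self._column(design[:, j], mu[j], sigma[j], gamma[j])
        self.log_row_product = self.log_factor.sum(axis=1)

    @staticmethod
    def _column(x: np.ndarray, mu: float, sigma: float, gamma: float) -> np.ndarray:
        g = min(max(gamma, GAMMA_CLAMP), 1.0 - GAMMA_CLAMP)
        return np.logaddexp(np.log(g) + log_mgf_term(x, mu, sigma), np.log1p(-g))

    def refresh_column(self, j: int, mu: float, sigma: float, gamma: float) -> None:
        new = self._column(self.design[:, j], mu, sigma, gamma)
        self.log_row_product += new - self.log_factor[:, j]
        self.log_factor[:, j] = new

    def rebuild_row_products(self) -> None:
        self.log_row_product = self.log_factor.sum(axis=1)

    def log_excluded(self, j: int) -> np.ndarray:
        """log P_j(x_r) for every subject r (empty product = 0 when p = 1)."""
        return self.log_row_product - self.log_factor[:, j]

    def check_consistency(self, tol: float = 1e-10) -> None:
        drift = np.abs(self.log_factor.sum(axis=1) - self.log_row_product).max()
        if drift > tol * max(1.0, np.abs(self.log_row_product).max()):
            raise RuntimeError(f"stale log-factor cache: row-product drift {drift:.3e}")


def log_excluded_product(cache: LogFactorCache, subject: int, j: int) -> float:
    """log P_j for one subject; checks the cache before answering."""
    cache.check_consistency()
    return float(cache.log_excluded(j)[subject])


def expected_log_partial_likelihood_mc(
    data: SurvivalDataset,
    risk: RiskSetIndex | None,
    params,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of E_Q[log L_p(D; beta)] with its standard error.

    ``params`` carries (mu, sigma, gamma); beta is drawn coordinatewise as
    gamma_j N(mu_j, sigma_j^2) + (1 - gamma_j) delta_0.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prefix = RiskPrefix.from_dataset(data)
    mu = np.asarray(params.mu, dtype=float)
    sigma = np.asarray(params.sigma, dtype=float)
    gamma = np.asarray(params.gamma, dtype=float)
    p = mu.shape[0]
    z = rng.random((n_draws, p)) < gamma
    beta = np.where(z, mu + sigma * rng.standard_normal((n_draws, p)), 0.0)
    eta_sorted = beta @ prefix.design_sorted.T          # (n_draws, n)
    eta_events = beta @ prefix.event_design.T           # (n_draws, n_events)
    vals = eta_events.sum(axis=1) - prefix.event_logsumexp(eta_sorted)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else 0.0
    return mean, se
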