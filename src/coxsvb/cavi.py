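"""Coordinate-ascent variational inference for the spike-and-slab Cox model.

Prior (per coefficient): beta_j | z_j ~ z_j Laplace(lam) + (1 - z_j) delta_0,
z_j | w_j ~ Bernoulli(w_j), w_j ~ Beta(a0, b0).  Variational family:
mean-field products of gamma_j N(mu_j, sigma_j^2) + (1 - gamma_j) delta_0.

Because the partial likelihood couples all subjects through risk-set sums,
the exact KL objective is intractable; the algorithm instead minimizes a
surrogate obtained by pushing the expectation inside the risk-set sum
(E log sum <= log sum E), which turns each risk-set term into
log sum_r M(x_rj, mu_j, sigma_j) P_j(x_r) with M the slab MGF factor and
P_j the product over the other coordinates.  Each coordinate update is a
one-dimensional problem:

* mu_j   <- argmin f(mu_j)    (risk-set term minus mu_j x_ij, plus the
                               Laplace penalty lam E|beta_j|)
* sigma_j <- argmin g(sigma_j) (risk-set term plus penalty minus log sigma_j,
                               the entropy barrier that prevents slab collapse)
* gamma_j <- sigmoid(zeta_j)  with
  zeta_j = log(a0/b0) - lam E|beta_j| - [likelihood cost of inclusion]
           + log(lam sigma_j sqrt(2 pi) / 2) + 1/2,
  the last two terms being E_N[log Laplace-slab] + Normal entropy with the
  lam E|beta_j| part split off.

mu and sigma are minimized by bounded Brent iterations (the objectives are
smooth and unimodal in practice); sigma on the log scale over
[1e-4, 10].  Coordinates are swept in ascending order, mu then sigma then
gamma, until the total absolute parameter change over a sweep drops below
the tolerance (default 1e-3).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import special

from .data import SurvivalDataset
from .likelihood import (
    GAMMA_CLAMP,
    LogFactorCache,
    RiskPrefix,
    _affine_event_lse,
)

logger = logging.getLogger("coxsvb")

__all__ = [
    "PriorSpec",
    "VariationalParams",
    "FitResult",
    "CaviWorkspace",
    "initialize",
    "fit",
]

SIGMA_BRACKET = (1e-4, 10.0)  # sigma searched on the log scale over this range
MU_HALF_WIDTH = 5.0           # initial mu bracket: current value +/- 5
XATOL = 1e-6

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_SQRT_2 = math.sqrt(2.0)


def _lam_e_abs(mu: float, sigma: float, lam: float) -> float:
    """Scalar lam * E|N(mu, sigma^2)| (hot path of the objectives)."""
    z = mu / sigma
    return lam * (
        sigma * _SQRT_2_OVER_PI * math.exp(-0.5 * z * z)
        + mu * math.erf(z / _SQRT_2)
    )


@njit(cache=True)
def _obj_1d(kind, t, other, lam, x, x2, logp, ends_sorted, xev):  # pragma: no cover
    """Coordinate objective: kind 0 = f(mu_j) with other = sigma_j;
    kind 1 = g on the log scale, t = log sigma_j with other = mu_j."""
    if kind == 0:
        mu, sigma = t, other
        lse = _affine_event_lse(mu, 0.5 * sigma * sigma, x, x2, logp, ends_sorted)
        extra = -mu * xev
    else:
        sigma = np.exp(t)
        mu = other
        lse = _affine_event_lse(mu, 0.5 * sigma * sigma, x, x2, logp, ends_sorted)
        extra = -t  # the -log sigma entropy barrier
    z = mu / sigma
    pen = lam * (
        sigma * 0.7978845608028654 * np.exp(-0.5 * z * z)
        + mu * math.erf(z * 0.7071067811865476)
    )
    return lse + extra + pen


@njit(cache=True)
def _fminbound(kind, lo, hi, other, lam, xa, xa2, logp, ends_sorted, xev, xatol):  # pragma: no cover
    """Bounded 1-D minimization: golden-section with parabolic interpolation
    (Brent), the classic fminbound scheme.  Returns (argmin, min value)."""
    maxfun = 200
    sqrt_eps = 1.4901161193847656e-08
    golden_mean = 0.3819660112501051
    a, b = lo, hi
    fulc = a + golden_mean * (b - a)
    nfc, xf = fulc, fulc
    rat = 0.0
    e = 0.0
    x = xf
    fx = _obj_1d(kind, x, other, lam, xa, xa2, logp, ends_sorted, xev)
    num = 1
    ffulc = fx
    fnfc = fx
    xm = 0.5 * (a + b)
    tol1 = sqrt_eps * abs(xf) + xatol / 3.0
    tol2 = 2.0 * tol1
    while abs(xf - xm) > (tol2 - 0.5 * (b - a)):
        golden = True
        if abs(e) > tol1:
            golden = False
            r = (xf - nfc) * (fx - ffulc)
            q = (xf - fulc) * (fx - fnfc)
            p = (xf - fulc) * q - (xf - nfc) * r
            q = 2.0 * (q - r)
            if q > 0.0:
                p = -p
            q = abs(q)
            r = e
            e = rat
            if (abs(p) < abs(0.5 * q * r)) and (p > q * (a - xf)) and (p < q * (b - xf)):
                rat = p / q
                x = xf + rat
                if ((x - a) < tol2) or ((b - x) < tol2):
                    si = 1.0 if xm - xf >= 0 else -1.0
                    rat = tol1 * si
            else:
                golden = True
        if golden:
            if xf >= xm:
                e = a - xf
            else:
                e = b - xf
            rat = golden_mean * e
        si = 1.0 if rat >= 0 else -1.0
        x = xf + si * max(abs(rat), tol1)
        fu = _obj_1d(kind, x, other, lam, xa, xa2, logp, ends_sorted, xev)
        num += 1
        if fu <= fx:
            if x >= xf:
                a = xf
            else:
                b = xf
            fulc, ffulc = nfc, fnfc
            nfc, fnfc = xf, fx
            xf, fx = x, fu
        else:
            if x < xf:
                a = x
            else:
                b = x
            if (fu <= fnfc) or (nfc == xf):
                fulc, ffulc = nfc, fnfc
                nfc, fnfc = x, fu
            elif (fu <= ffulc) or (fulc == xf) or (fulc == nfc):
                fulc, ffulc = x, fu
        xm = 0.5 * (a + b)
        tol1 = sqrt_eps * abs(xf) + xatol / 3.0
        tol2 = 2.0 * tol1
        if num >= maxfun:
            break
    return xf, fx


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: Laplace slab rate lam, Beta(a0, b0) inclusion prior.

    a0/(a0+b0) is the a-priori proportion of nonzero coefficients; lam
    controls slab shrinkage (larger = more shrinkage).
    """

    lam: float
    a0: float
    b0: float

    def __post_init__(self):
        for name in ("lam", "a0", "b0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class VariationalParams:
    """Mean-field parameters: slab means mu, slab sds sigma, inclusion gamma."""

    mu: np.ndarray
    sigma: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).copy()
        self.sigma = np.asarray(self.sigma, dtype=float).copy()
        self.gamma = np.asarray(self.gamma, dtype=float).copy()
        if not (self.mu.shape == self.sigma.shape == self.gamma.shape):
            raise ValueError("mu, sigma, gamma must share a common length")
        if not np.all(self.sigma > 0):
            raise ValueError("sigma must be strictly positive")
        if np.any(self.gamma < 0) or np.any(self.gamma > 1):
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def copy(self) -> "VariationalParams":
        return VariationalParams(self.mu, self.sigma, self.gamma)


@dataclass
class FitResult:
    params: VariationalParams
    converged: bool
    n_iterations: int
    trajectory: list[float]        # total absolute parameter change per sweep
    settings: dict = field(default_factory=dict)
    diagnostics: dict | None = None

    def to_dict(self) -> dict:
        return {
            "mu": self.params.mu.tolist(),
            "sigma": self.params.sigma.tolist(),
            "gamma": self.params.gamma.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "trajectory": list(self.trajectory),
            "settings": self.settings,
        }


class CaviWorkspace:
    """Mutable state for one fit: sorted risk prefixes, cache, parameters.

    Exposes the per-coordinate objectives and updates so they can be
    inspected and unit-tested; :func:`fit` drives the sweep loop.
    """

    def __init__(self, data: SurvivalDataset, prior: PriorSpec, params: VariationalParams):
        if params.p != data.p:
            raise ValueError("parameter length does not match design")
        self.prior = prior
        self.params = params.copy()
        self.prefix = RiskPrefix.from_dataset(data)
        self.X = self.prefix.design_sorted
        self.Xsq = self.X**2
        # per-coordinate sum over event subjects of x_ij
        self.x_event_sum = self.prefix.event_design.sum(axis=0)
        self.cache = LogFactorCache(
            self.X, self.params.mu, self.params.sigma, self.params.gamma
        )

    # -- objectives ----------------------------------------------------

    def _event_term(self, j: int, mu: float, sigma: float, log_pj: np.ndarray) -> float:
        return self.prefix.affine_event_logsumexp(
            mu, 0.5 * sigma * sigma, self.X[:, j], self.Xsq[:, j], log_pj
        )

    def objective_mu(self, j: int, mu: float, log_pj: np.ndarray | None = None) -> float:
        """f(mu_j): risk-set surrogate minus mu_j x_ij plus lam E|beta_j|."""
        if log_pj is None:
            log_pj = self.cache.log_excluded(j)
        sigma = self.params.sigma[j]
        return (
            self._event_term(j, mu, sigma, log_pj)
            - mu * self.x_event_sum[j]
            + _lam_e_abs(mu, sigma, self.prior.lam)
        )

    def objective_sigma(self, j: int, sigma: float, log_pj: np.ndarray | None = None) -> float:
        """g(sigma_j): risk-set surrogate plus lam E|beta_j| minus log sigma_j."""
        if sigma <= 0:
            raise ValueError("sigma must be strictly positive")
        if log_pj is None:
            log_pj = self.cache.log_excluded(j)
        mu = self.params.mu[j]
        return (
            self._event_term(j, mu, sigma, log_pj)
            + _lam_e_abs(mu, sigma, self.prior.lam)
            - math.log(sigma)
        )

    def zeta(self, j: int, log_pj: np.ndarray | None = None) -> float:
        """Logit of the inclusion probability gamma_j at the current (mu, sigma)."""
        if log_pj is None:
            log_pj = self.cache.log_excluded(j)
        mu, sigma = self.params.mu[j], self.params.sigma[j]
        lam = self.prior.lam
        with_m = self._event_term(j, mu, sigma, log_pj)
        without_m = self.prefix.event_logsumexp(log_pj)
        delta_lik = with_m - without_m - mu * self.x_event_sum[j]
        return (
            math.log(self.prior.a0 / self.prior.b0)
            - _lam_e_abs(mu, sigma, lam)
            - delta_lik
            + math.log(lam * sigma * math.sqrt(2.0 * math.pi) / 2.0)
            + 0.5
        )

    # -- coordinate updates --------------------------------------------

    def update_mu(self, j: int, log_pj: np.ndarray | None = None) -> float:
        """Set mu_j to a bracketed Brent minimizer of f; never uphill."""
        if log_pj is None:
            log_pj = self.cache.log_excluded(j)
        current = self.params.mu[j]
        f_current = self.objective_mu(j, current, log_pj)
        half = MU_HALF_WIDTH
        best_x, best_f = current, f_current
        for _ in range(4):  # initial bracket plus up to 3 expansions
            xk, fk = _fminbound(
                0, current - half, current + half, self.params.sigma[j],
                self.prior.lam, self.X[:, j], self.Xsq[:, j], log_pj,
                self.prefix.ends_sorted, self.x_event_sum[j], XATOL,
            )
            if fk < best_f:
                best_x, best_f = float(xk), float(fk)
            at_edge = min(xk - (current - half), (current + half) - xk) < 1e-3 * half
            if not at_edge:
                break
            half *= 2.0
        if best_f > f_current:  # optimizer failure: keep previous value
            logger.debug("mu update for coordinate %d did not descend; kept", j)
            best_x = current
        self.params.mu[j] = best_x
        return best_x

    def update_sigma(self, j: int, log_pj: np.ndarray | None = None) -> float:
        """Set sigma_j to the Brent minimizer of g on a log-scale bracket."""
        if log_pj is None:
            log_pj = self.cache.log_excluded(j)
        current = self.params.sigma[j]
        g_current = self.objective_sigma(j, current, log_pj)
        lo_lim, hi_lim = np.log(SIGMA_BRACKET[0]), np.log(SIGMA_BRACKET[1])
        # start from a window around the current value, expanding toward the
        # full [1e-4, 10] log-scale bracket on boundary hits
        lo = max(np.log(current) - 1.5, lo_lim)
        hi = min(np.log(current) + 1.5, hi_lim)
        best_x, best_f = current, g_current
        for _ in range(4):
            uk, fk = _fminbound(
                1, lo, hi, self.params.mu[j],
                self.prior.lam, self.X[:, j], self.Xsq[:, j], log_pj,
                self.prefix.ends_sorted, self.x_event_sum[j], XATOL,
            )
            if fk < best_f:
                best_x, best_f = float(np.exp(uk)), float(fk)
            at_edge = min(uk - lo, hi - uk) < 1e-3
            full = lo <= lo_lim + 1e-12 and hi >= hi_lim - 1e-12
            if not at_edge or full:
                break
            lo = max(lo - 3.0, lo_lim)
            hi = min(hi + 3.0, hi_lim)
        if best_f > g_current:
            logger.debug("sigma update for coordinate %d did not descend; kept", j)
            best_x = current
        self.params.sigma[j] = best_x
        return best_x

    def update_gamma(self, j: int, log_pj: np.ndarray | None = None) -> float:
        """Set gamma_j = sigmoid(zeta_j), clamped away from {0, 1}."""
        z = self.zeta(j, log_pj)
        g = float(np.clip(special.expit(z), GAMMA_CLAMP, 1.0 - GAMMA_CLAMP))
        self.params.gamma[j] = g
        return g

    def sweep(self, track: list | None = None) -> float:
        """One pass over coordinates 1..p; returns total absolute change."""
        old_mu = self.params.mu.copy()
        old_sigma = self.params.sigma.copy()
        old_gamma = self.params.gamma.copy()
        for j in range(self.params.p):
            log_pj = self.cache.log_excluded(j)
            if track is not None:
                f_before = self.objective_mu(j, self.params.mu[j], log_pj)
            self.update_mu(j, log_pj)
            if track is not None:
                f_after = self.objective_mu(j, self.params.mu[j], log_pj)
                g_before = self.objective_sigma(j, self.params.sigma[j], log_pj)
            self.update_sigma(j, log_pj)
            if track is not None:
                g_after = self.objective_sigma(j, self.params.sigma[j], log_pj)
                track.append((j, f_after - f_before, g_after - g_before))
            self.update_gamma(j, log_pj)
            self.cache.refresh_column(
                j, self.params.mu[j], self.params.sigma[j], self.params.gamma[j]
            )
        self.cache.rebuild_row_products()  # guard against incremental drift
        return float(
            np.abs(self.params.mu - old_mu).sum()
            + np.abs(self.params.sigma - old_sigma).sum()
            + np.abs(self.params.gamma - old_gamma).sum()
        )


def initialize(
    data: SurvivalDataset,
    seed: int | None = None,
    sigma0: float = 0.05,
    gamma0: float = 0.5,
    max_nonzero: int | None = None,
) -> VariationalParams:
    """Starting point: mu from a lightly penalized l1 Cox fit, sigma = 0.05,
    gamma = 0.5.

    The slab means correspond to the (unshrunk) coefficient values were the
    variables included, so the l1 path is walked to the smallest penalty
    keeping at most min(n/2, 200) coefficients nonzero.  If the l1 fit
    fails, mu falls back to zeros with a warning.
    """
    p = data.p
    cap = max_nonzero if max_nonzero is not None else min(data.n // 2, 200)
    mu = np.zeros(p)
    try:
        mu = _l1_cox_path_means(data, cap)
    except Exception as exc:  # noqa: BLE001 - any failure falls back to zeros
        logger.warning("l1 initializer failed (%s); starting from mu = 0", exc)
    return VariationalParams(
        mu=mu, sigma=np.full(p, sigma0), gamma=np.full(p, gamma0)
    )


def _l1_cox_path_means(data: SurvivalDataset, cap: int) -> np.ndarray:
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=data.events.astype(bool), time=data.times)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.01, fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(data.design, y)
    coefs = model.coef_  # (p, n_alphas), alphas decreasing
    nnz = (coefs != 0).sum(axis=0)
    ok = np.flatnonzero(nnz <= cap)
    col = ok[-1] if ok.size else 0  # last ok column = smallest admissible penalty
    return np.ascontiguousarray(coefs[:, col], dtype=float)


def fit(
    data: SurvivalDataset,
    prior: PriorSpec,
    init: VariationalParams | None = None,
    tol: float = 1e-3,
    max_iter: int = 1000,
    seed: int | None = None,
    track_objectives: bool = False,
) -> FitResult:
    """Run CAVI to convergence and return the variational parameters.

    Stops when the total absolute change in (mu, sigma, gamma) over a full
    sweep falls below ``tol`` (default 1e-3) or after ``max_iter`` sweeps
    (converged flag False; the result is still returned).

    With ``track_objectives`` the per-update changes in the printed
    objectives f and g are recorded in ``diagnostics["objective_deltas"]``
    (positive entries would mean an uphill update).
    """
    if init is None:
        init = initialize(data, seed=seed)
    ws = CaviWorkspace(data, prior, init)
    trajectory: list[float] = []
    deltas: list | None = [] if track_objectives else None
    converged = False
    for it in range(1, max_iter + 1):
        change = ws.sweep(track=deltas)
        trajectory.append(change)
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("CAVI did not converge in %d sweeps (last change %.3g)",
                       max_iter, trajectory[-1] if trajectory else float("nan"))
    result = FitResult(
        params=ws.params.copy(),
        converged=converged,
        n_iterations=len(trajectory),
        trajectory=trajectory,
        settings={
            "lam": prior.lam, "a0": prior.a0, "b0": prior.b0,
            "tol": tol, "max_iter": max_iter, "seed": seed,
        },
        diagnostics={"objective_deltas": deltas} if track_objectives else None,
    )
    return result
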