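"""Posterior summaries: selection, credible sets, FDR, ELBO, concordance."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from coxsvb import (
    PriorSpec,
    VariationalParams,
    bayesian_fdr_threshold,
    build_risk_sets,
    concordance_index,
    coverage_and_size,
    credible_set,
    credible_sets,
    elbo_mc,
    kl_q_prior,
    log_partial_likelihood,
    posterior_mean,
    prognostic_index,
    risk_comparison_matrix,
    risk_comparison_prob,
    select_at_half,
)

from conftest import random_survival, random_params
from _oracles import pairwise_cindex


def make_params(mu, sigma, gamma):
    return VariationalParams(mu=np.atleast_1d(np.asarray(mu, float)),
                             sigma=np.atleast_1d(np.asarray(sigma, float)),
                             gamma=np.atleast_1d(np.asarray(gamma, float)))


class TestPointEstimatesAndSelection:
    @pytest.mark.parametrize(
        "gamma,mu,expected",
        [(0.0, 5.0, 0.0), (1.0, 1.3, 1.3), (0.5, 2.0, 1.0)],
    )
    def test_posterior_mean(self, gamma, mu, expected):
        params = make_params([mu], [0.1], [gamma])
        assert posterior_mean(params)[0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "gamma,expected",
        [
            ([0.6, 0.4, 0.5], [0, 2]),
            ([0.1, 0.2, 0.3], []),
            ([0.5, 0.5], [0, 1]),      # threshold is inclusive
        ],
    )
    def test_select_at_half(self, gamma, expected):
        params = make_params(np.zeros(len(gamma)), np.ones(len(gamma)), gamma)
        assert select_at_half(params).tolist() == expected


class TestCredibleSets:
    def test_spike_branch(self):
        s = credible_set(make_params([1.0], [0.2], [0.02]), 0)
        assert s.kind == "spike_only"
        assert s.lebesgue_size == 0.0
        assert s.contains(0.0) and not s.contains(0.01)

    def test_interval_branch_matches_root_finding(self):
        g, mu, sigma = 0.99, 1.0, 0.1
        s = credible_set(make_params([mu], [sigma], [g]), 0)
        assert s.kind == "interval"
        z = optimize.brentq(lambda t: g * (2 * stats.norm.cdf(t) - 1) - 0.95,
                            1e-6, 10.0)
        assert s.lebesgue_size == pytest.approx(2 * z * sigma, rel=1e-8)
        assert s.lower <= mu <= s.upper

    def test_union_branch_closed_form(self):
        # spike holds 0.5 mass, so the slab interval needs mass 0.9
        s = credible_set(make_params([0.0], [1.0], [0.5]), 0)
        assert s.kind == "interval_plus_spike"
        assert s.upper == pytest.approx(stats.norm.ppf(0.95), abs=1e-6)
        assert s.lower == pytest.approx(-stats.norm.ppf(0.95), abs=1e-6)

    def test_mass_accounting_random_triples(self, rng):
        """Total variational probability of S_j must reach the level."""
        level = 0.95
        for _ in range(200):
            g = rng.uniform(0, 1)
            mu = rng.normal(0, 2)
            sigma = rng.uniform(0.01, 2.0)
            s = credible_set(make_params([mu], [sigma], [g]), 0, level=level)
            slab_mass = 0.0
            if s.kind != "spike_only":
                slab_mass, _ = integrate.quad(
                    lambda b: stats.norm.pdf(b, mu, sigma), s.lower, s.upper
                )
            spike_in = (s.kind == "spike_only"
                        or s.kind == "interval_plus_spike"
                        or s.lower <= 0.0 <= s.upper)
            mass = g * slab_mass + (1 - g) * spike_in
            assert mass >= level - 1e-6

    def test_coverage_and_size_summary(self):
        sets = [
            credible_set(make_params([1.0], [0.05], [0.99]), 0),   # tight near 1
            credible_set(make_params([0.0], [0.1], [0.01]), 0),    # spike
        ]
        out = coverage_and_size(sets, np.array([1.0, 0.0]))
        assert out["coverage_nonzero"] == 1.0
        assert out["coverage_zero"] == 1.0
        assert out["size_zero"] == 0.0
        assert out["size_nonzero"] > 0.0
        missed = coverage_and_size(
            [credible_set(make_params([0.0], [0.1], [0.01]), 0)], np.array([1.0])
        )
        assert missed["coverage_nonzero"] == 0.0


class TestBayesianFdr:
    def test_documented_examples(self):
        r = bayesian_fdr_threshold(np.array([0.99, 0.98, 0.6, 0.1]), alpha=0.1)
        assert r.selected.tolist() == [0, 1]
        assert r.bayes_fdr_at_threshold == pytest.approx(0.015)
        r2 = bayesian_fdr_threshold(np.array([0.99, 0.99]), alpha=0.1)
        assert r2.selected.tolist() == [0, 1]
        assert r2.bayes_fdr_at_threshold == pytest.approx(0.01)
        r3 = bayesian_fdr_threshold(np.array([0.5, 0.5]), alpha=0.1)
        assert r3.selected.size == 0 and not r3.qualifying

    def test_largest_admissible_threshold_set(self, rng):
        alpha = 0.2
        for _ in range(25):
            gamma = np.round(rng.uniform(0, 1, size=10), 3)
            r = bayesian_fdr_threshold(gamma, alpha)
            # enumerate every threshold-achievable set {gamma >= v}
            best = np.array([], dtype=int)
            for v in np.unique(gamma):
                if v == 0.0:
                    continue
                sel = np.flatnonzero(gamma >= v)
                fdr = (1 - gamma[sel]).sum() / sel.size
                if fdr < alpha and sel.size > best.size:
                    best = sel
            assert r.selected.tolist() == best.tolist()
            if r.qualifying:
                assert r.bayes_fdr_at_threshold < alpha

    def test_all_zero_gamma_flagged_empty(self):
        r = bayesian_fdr_threshold(np.zeros(4), alpha=0.1)
        assert r.selected.size == 0 and not r.qualifying


class TestElbo:
    def test_spike_only_posterior_closed_form(self, rng):
        ds = random_survival(rng, n=20, p=4)
        prior = PriorSpec(lam=1.0, a0=1.0, b0=4.0)
        params = make_params(np.zeros(4), np.full(4, 0.3), np.zeros(4))
        elbo, se = elbo_mc(ds, None, params, prior, n_draws=100, seed=0)
        w = prior.a0 / (prior.a0 + prior.b0)
        expected = (log_partial_likelihood(ds, build_risk_sets(ds), np.zeros(4))
                    + 4 * math.log(1 - w))
        assert elbo == pytest.approx(expected, rel=1e-10)
        assert se == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("variant", ["collapsed", "beta"])
    def test_kl_nonnegative(self, rng, variant):
        prior = PriorSpec(lam=0.8, a0=2.0, b0=10.0)
        for _ in range(30):
            params = random_params(rng, 6)
            assert kl_q_prior(params, prior, variant=variant) >= -1e-9

    def test_kl_zero_when_q_matches_collapsed_prior(self):
        # gamma at the prior inclusion probability and a slab matching the
        # Laplace as closely as a Normal can leaves a strictly positive but
        # small KL; the Bernoulli part alone must vanish
        prior = PriorSpec(lam=1.0, a0=1.0, b0=3.0)
        params = make_params([0.0], [0.8], [0.25])
        kl_full = kl_q_prior(params, prior)
        params_spike = make_params([0.0], [0.8], [1e-14])
        # removing the slab contribution leaves ~ -log(1 - w)
        assert kl_full > 0.0
        assert kl_q_prior(params_spike, prior) == pytest.approx(
            -math.log(1 - 0.25), abs=1e-6
        )


class TestPrognosticIndexAndConcordance:
    def test_prognostic_index_linear(self, rng):
        ds = random_survival(rng, n=10, p=3)
        beta = np.array([2.0, 0.0, -1.0])
        np.testing.assert_allclose(prognostic_index(ds, beta), ds.design @ beta)

    def test_median_split_sizes(self, rng):
        ds = random_survival(rng, n=11, p=1)
        eta = prognostic_index(ds, np.array([1.0]))
        high = eta >= np.median(eta)
        assert high.sum() in (5, 6) and (~high).sum() in (5, 6)

    def test_perfect_ranking(self):
        # higher risk score fails first
        c = concordance_index([1.0, 2.0, 3.0], [1, 1, 1], [3.0, 2.0, 1.0])
        assert c == 1.0

    def test_constant_scores_give_half(self):
        c = concordance_index([1.0, 2.0, 3.0], [1, 1, 1], [0.5, 0.5, 0.5])
        assert c == 0.5

    def test_matches_pairwise_oracle_and_lifelines(self, rng):
        lifelines_utils = pytest.importorskip("lifelines.utils")
        ds = random_survival(rng, n=40, p=2, beta=np.array([1.0, -0.5]))
        eta = prognostic_index(ds, np.array([1.0, -0.5]))
        ours = concordance_index(ds.times, ds.events, eta)
        oracle = pairwise_cindex(ds.times, ds.events, eta)
        assert ours == pytest.approx(oracle, abs=1e-12)
        ll = lifelines_utils.concordance_index(ds.times, -eta, ds.events)
        assert ours == pytest.approx(ll, abs=1e-10)

    def test_invariant_to_monotone_transform(self, rng):
        ds = random_survival(rng, n=25, p=1, beta=np.array([1.0]))
        eta = prognostic_index(ds, np.array([1.0]))
        a = concordance_index(ds.times, ds.events, eta)
        b = concordance_index(ds.times, ds.events, np.exp(2.0 * eta))
        assert a == b

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError, match="no comparable"):
            concordance_index([1.0, 2.0], [0, 1], [0.1, 0.2])


class TestRiskComparison:
    def test_identical_subjects(self):
        params = make_params([1.0], [0.5], [0.9])
        x = np.array([1.0])
        assert risk_comparison_prob(params, x, x, n_draws=100, seed=0) == 1.0

    def test_point_mass_indicator(self):
        params = make_params([2.0], [1e-12], [1.0])
        assert risk_comparison_prob(params, np.array([1.0]), np.array([0.0]),
                                    n_draws=100, seed=0) == 1.0
        assert risk_comparison_prob(params, np.array([0.0]), np.array([1.0]),
                                    n_draws=100, seed=0) == 0.0

    def test_symmetric_normal_is_half(self):
        params = make_params([0.0], [1.0], [1.0])
        p = risk_comparison_prob(params, np.array([1.0]), np.array([0.0]),
                                 n_draws=20_000, seed=1)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_reproducible(self):
        params = make_params([0.3, -0.2], [0.5, 0.5], [0.7, 0.6])
        args = (params, np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert (risk_comparison_prob(*args, n_draws=500, seed=5)
                == risk_comparison_prob(*args, n_draws=500, seed=5))

    def test_matrix_complement_bound(self, rng):
        params = random_params(rng, 3)
        X = rng.standard_normal((5, 3))
        mat = risk_comparison_matrix(params, X, n_draws=400, seed=2)
        assert np.all(mat + mat.T >= 1.0 - 1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
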