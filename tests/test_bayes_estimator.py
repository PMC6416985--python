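"""Bayesian estimator: prior, truncated sampling, summaries, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import invgamma

import recapture as rc
from recapture.bayes_estimator import (
    ConvergenceReport,
    PosteriorDraws,
    PriorConfig,
    hpdi,
    log_prior,
    split_rhat,
)
from recapture.ml_estimator import marginalize_sources

from conftest import table_from_counts


class TestModelSpace:
    def test_source_only_space_has_64_models(self):
        space = rc.enumerate_model_space(covariates=False)
        assert space.n_models == 64
        models = list(space.models())
        assert frozenset() in models  # minimal: main effects only
        assert frozenset(space.optional_terms) in models  # maximal

    def test_covariate_space_has_21_optional_terms(self):
        space = rc.enumerate_model_space(covariates=True)
        assert len(space.optional_terms) == 21
        assert space.n_models == 2**21

    def test_main_effects_never_optional(self):
        space = rc.enumerate_model_space(covariates=True)
        for term in space.optional_terms:
            assert len(term) == 2  # only pairwise interactions are optional


class TestLogPrior:
    def test_zero_beta_maximises_normal_factor(self):
        X = np.column_stack([np.ones(8), np.linspace(-1, 1, 8)])
        base = log_prior(np.zeros(2), 1.0, X)
        for b in ([0.5, 0.0], [0.0, -0.4], [1.0, 1.0]):
            assert log_prior(np.array(b), 1.0, X) <= base

    def test_sigma2_scaling_identity(self):
        X = np.column_stack([np.ones(8), np.linspace(-1, 1, 8)])
        beta = np.array([0.3, -0.7])
        pc = PriorConfig(a=2.0, b=1.0)
        n, p = X.shape
        xtx = X.T @ X
        quad = beta @ xtx @ beta
        got = log_prior(beta, 2.0, X, pc) - log_prior(beta, 1.0, X, pc)
        want = (
            -0.5 * p * math.log(2.0)
            + quad / (2 * n) * (1 - 0.5)
            + invgamma.logpdf(2.0, pc.a, scale=pc.b)
            - invgamma.logpdf(1.0, pc.a, scale=pc.b)
        )
        assert got == pytest.approx(want, rel=1e-10)

    def test_prior_integrates_to_one_on_toy(self):
        # one coefficient, well-behaved hyperparameters; integrate the
        # joint density over (beta, sigma^2) by adaptive quadrature
        X = np.linspace(0.5, 1.5, 6)[:, None]
        pc = PriorConfig(a=3.0, b=2.0)

        def dens(beta, s2):
            return math.exp(log_prior(np.array([beta]), s2, X, pc))

        val, err = integrate.dblquad(
            dens, 1e-6, np.inf, lambda s2: -np.inf, lambda s2: np.inf,
            epsabs=1e-9, epsrel=1e-9,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            log_prior(np.zeros(2), 1.0, X)


class TestTruncatedPoisson:
    def test_zero_bound_forces_zero(self):
        rng = np.random.default_rng(0)
        assert all(rc.sample_truncated_poisson(50.0, 0, rng) == 0 for _ in range(200))

    def test_infinite_bound_matches_poisson_mean(self):
        rng = np.random.default_rng(1)
        draws = [rc.sample_truncated_poisson(4.2, np.inf, rng) for _ in range(20_000)]
        assert np.mean(draws) == pytest.approx(4.2, abs=3 * math.sqrt(4.2 / 20_000))

    def test_invalid_arguments(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            rc.sample_truncated_poisson(0.0, 3, rng)
        with pytest.raises(ValueError):
            rc.sample_truncated_poisson(1.0, -1, rng)


class TestHpdi:
    def test_point_mass_window(self):
        draws = np.array([0.0] * 99 + [10.0])
        assert hpdi(draws, 0.95) == (0.0, 0.0)

    def test_contains_mass(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        lo, hi = hpdi(x, 0.95)
        inside = np.mean((x >= lo) & (x <= hi))
        assert 0.94 <= inside <= 0.96
        assert hi - lo < np.quantile(x, 0.975) - np.quantile(x, 0.025) + 0.05


def _toy_two_source_table():
    table = table_from_counts({(1, 0, 0, 0): 30, (0, 1, 0, 0): 20, (1, 1, 0, 0): 10})
    return marginalize_sources(table, ("DR", "PB"))


class TestMcmcSample:
    def test_same_seed_same_draws(self, default_table):
        cens = rc.mark_censored_cells(default_table)
        a = rc.mcmc_sample(cens, variant=2, n_iter=800, seed=5)
        b = rc.mcmc_sample(cens, variant=2, n_iter=800, seed=5)
        np.testing.assert_array_equal(a.N, b.N)
        np.testing.assert_array_equal(a.model_index, b.model_index)

    def test_abundance_never_below_observed(self, default_table):
        cens = rc.mark_censored_cells(default_table)
        d = rc.mcmc_sample(cens, variant=2, n_iter=1500, seed=1)
        assert (d.N >= d.n_observed).all()

    def test_zero_bound_censored_cell(self, toy_histories):
        h = toy_histories[toy_histories["study_id"] != "b"]
        cens = rc.mark_censored_cells(rc.build_contingency_table(h, 2012))
        d = rc.mcmc_sample(cens, variant=2, n_iter=1000, seed=2)
        # the PB-only cell is bound to zero, so N = observed + missing only
        assert (d.N >= d.n_observed).all()
        assert d.n_observed == 4

    def test_variant3_requires_strata(self, default_table):
        with pytest.raises(ValueError):
            rc.mcmc_sample(default_table, variant=3, n_iter=100)

    def test_invalid_variant(self, default_table):
        with pytest.raises(ValueError):
            rc.mcmc_sample(default_table, variant=4, n_iter=100)

    def test_fixed_model_restricts_chain(self):
        cells = _toy_two_source_table()
        d = rc.mcmc_sample(cells, variant=1, n_iter=2000, seed=4, fixed_model=frozenset())
        assert d.model_catalog == [()]
        est = rc.bma_abundance(d, min_draws=500)
        assert est.model_probabilities == {(): 1.0}

    def test_variant1_treats_censored_as_observed(self, default_table):
        cens = rc.mark_censored_cells(default_table)
        d1 = rc.mcmc_sample(cens, variant=1, n_iter=1500, seed=6)
        d2 = rc.mcmc_sample(cens, variant=2, n_iter=1500, seed=6)
        assert d1.n_observed > d2.n_observed  # PB-only cells counted only in v1

    def test_censoring_monotonicity(self, default_sim):
        # with heavy PB contamination the censored variant sits below the
        # uncensored one
        hist = rc.histories_from_truth(default_sim.truth)
        table = rc.mark_censored_cells(rc.build_contingency_table(hist, 2012))
        m1 = rc.bma_abundance(rc.mcmc_sample(table, 1, n_iter=4000, seed=0)).median
        m2 = rc.bma_abundance(rc.mcmc_sample(table, 2, n_iter=4000, seed=0)).median
        assert m2 < m1


class TestSummaries:
    def test_model_probabilities_sum_to_one(self, default_table):
        d = rc.mcmc_sample(default_table, variant=1, n_iter=3000, seed=7)
        est = rc.bma_abundance(d)
        assert sum(est.model_probabilities.values()) == pytest.approx(1.0)
        assert est.hpdi[0] <= est.median <= est.hpdi[1]

    def test_too_few_draws_rejected(self, default_table):
        d = rc.mcmc_sample(default_table, variant=1, n_iter=500, seed=8)
        with pytest.raises(ValueError):
            rc.bma_abundance(d, min_draws=1000)

    def test_p_value_in_unit_interval(self, default_table):
        d = rc.mcmc_sample(default_table, variant=1, n_iter=2000, seed=9)
        p = rc.bayesian_p_value(d)
        assert 0.0 <= p <= 1.0


def _fake_draws(N, n_iter=None, burn_in=0.0):
    N = np.asarray(N, dtype=float)
    n = len(N)
    return PosteriorDraws(
        N=N,
        sigma2=np.ones(n),
        model_index=np.zeros(n, dtype=np.int32),
        chi2_obs=np.zeros(n),
        chi2_rep=np.zeros(n),
        model_catalog=[()],
        n_iter=n_iter or n,
        burn_in=burn_in,
        variant=1,
        seed=0,
        accept_beta=0.4,
        accept_rj=0.3,
        n_observed=0,
    )


class TestConvergence:
    def test_iid_chain_diagnostic_near_one(self):
        rng = np.random.default_rng(10)
        rhat = split_rhat(rng.normal(1000.0, 5.0, size=20_000))
        assert abs(rhat - 1.0) < 0.01

    def test_disjoint_segments_trigger_extension(self):
        x = np.concatenate([np.full(5000, 100.0), np.full(5000, 4000.0)])
        x += np.random.default_rng(0).normal(0, 1, size=10_000)
        draws = _fake_draws(x)
        report = rc.convergence_check(draws, extend_by=5000, max_total=40_000)
        assert report.rhat > 1.05
        assert not report.converged
        assert report.recommended_extension == 5000

    def test_extension_cap_honoured(self):
        x = np.concatenate([np.full(500, 100.0), np.full(500, 4000.0)])
        draws = _fake_draws(x, n_iter=1_400_000)
        report = rc.convergence_check(
            draws, extend_by=500_000, max_total=1_500_000
        )
        assert report.recommended_extension == 100_000
        assert report.capped

    def test_constant_chain_counts_as_converged(self):
        report = rc.convergence_check(_fake_draws(np.full(4000, 123.0)))
        assert report.converged

    def test_sample_with_extension_honours_cap(self, default_table):
        # an unreachable threshold forces extensions until the cap
        draws, report = rc.sample_with_extension(
            default_table, variant=1, n_iter=600, seed=1,
            threshold=0.5, extend_by=600, max_total=1800,
        )
        assert draws.n_iter == 1800
        assert not report.converged and report.recommended_extension == 0
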