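"""Gamma-Poisson probability engine: pmf, tails, sampling, regression."""

import numpy as np
import pytest
from scipy import integrate, special, stats

import nbburden as nb
from nbburden.nbmodel import _nb_loglik


def mixture_pmf_quadrature(y, mu, sigma):
    """Independent oracle: numerically integrate Poisson against the
    Gamma mixing density with shape 1/sigma and scale mu*sigma."""
    shape = 1.0 / sigma
    scale = mu * sigma

    def integrand(lam):
        return stats.poisson.pmf(y, lam) * stats.gamma.pdf(lam, a=shape, scale=scale)

    hi = max(mu + 50 * np.sqrt(mu * (1 + mu * sigma)), 50 * scale, 10.0)
    val, _ = integrate.quad(integrand, 0, hi, limit=200, epsabs=1e-13, epsrel=1e-11)
    return val


class TestPmf:
    def test_zero_count_closed_form(self):
        # P(0) = (1 + sigma*mu)^(-1/sigma)
        assert nb.nb_pmf(0, mu=2, sigma=0.5) == pytest.approx(0.25, abs=1e-12)

    def test_one_count_hand_evaluation(self):
        assert nb.nb_pmf(1, mu=2, sigma=0.5) == pytest.approx(0.25, abs=1e-12)

    def test_poisson_limit(self):
        expect = np.exp(-2) * 4 / 2
        assert nb.nb_pmf(2, mu=2, sigma=1e-10) == pytest.approx(expect, abs=1e-6)
        assert nb.nb_pmf(2, mu=2, sigma=0.0) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("mu", [0.5, 5.0, 40.0])
    @pytest.mark.parametrize("sigma", [0.05, 0.5, 1.5])
    def test_matches_mixture_quadrature(self, mu, sigma):
        for y in [0, 1, 3, 10, 25]:
            oracle = mixture_pmf_quadrature(y, mu, sigma)
            assert nb.nb_pmf(y, mu=mu, sigma=sigma) == pytest.approx(oracle, abs=1e-8)

    def test_mass_sums_to_one_and_moments(self):
        for mu, sigma in [(1, 0.2), (10, 1.0), (100, 2.0)]:
            sd = np.sqrt(mu * (1 + mu * sigma))
            ys = np.arange(0, int(mu + 25 * sd) + 1)
            pmf = nb.nb_pmf(ys, mu=mu, sigma=sigma)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-8)
            assert (pmf * ys).sum() == pytest.approx(mu, rel=1e-6)
            var = (pmf * ys**2).sum() - mu**2
            assert var == pytest.approx(mu * (1 + mu * sigma), rel=1e-5)

    def test_kl_to_poisson_shrinks_with_sigma(self):
        mu = 10.0
        ys = np.arange(0, 200)
        pois = stats.poisson.pmf(ys, mu)
        kls = []
        for sigma in [1.0, 0.3, 0.1, 0.01, 0.001]:
            p = nb.nb_pmf(ys, mu=mu, sigma=sigma)
            kls.append(float(np.sum(p * (np.log(p) - np.log(pois)))))
        assert all(a > b for a, b in zip(kls, kls[1:]))
        assert kls[-1] < 1e-4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nb.nb_pmf(-1, mu=2, sigma=0.5)
        with pytest.raises(ValueError):
            nb.nb_pmf(1.5, mu=2, sigma=0.5)
        with pytest.raises(ValueError):
            nb.nb_pmf(1, mu=0.0, sigma=0.5)


class TestTail:
    def test_zero_observed_is_one(self):
        assert nb.nb_tail_pvalue(0, mu=5, sigma=0.7) == 1.0

    def test_complement_of_pmf_at_one(self):
        assert nb.nb_tail_pvalue(1, mu=2, sigma=0.5) == pytest.approx(0.75, abs=1e-12)

    def test_matches_direct_summation(self):
        # P(Y >= 5) = 1 - sum_{k<5} pmf(k)
        direct = 1.0 - nb.nb_pmf(np.arange(5), mu=1, sigma=0.3).sum()
        assert nb.nb_tail_pvalue(5, mu=1, sigma=0.3) == pytest.approx(direct, rel=1e-10)

    def test_monotone_nonincreasing_in_y(self):
        ps = nb.nb_tail_pvalue(np.arange(0, 50), mu=8, sigma=0.4)
        assert (np.diff(ps) <= 1e-15).all()

    def test_deep_tail_is_stable_and_floored(self):
        p = nb.nb_tail_pvalue(100000, mu=1, sigma=0.01)
        assert 0 < p <= 1e-300 * 10 or p >= 1e-300
        assert nb.nb_tail_pvalue(10**6, mu=0.001, sigma=0.001) == 1e-300


class TestSampling:
    def test_moments_match_mixture(self):
        params = nb.NBParams(mu=5, sigma=0.4)
        draws = nb.sample_gamma_poisson(params, s_d=10, n=100_000, rng=7)
        se = np.sqrt(params.variance / len(draws))
        assert abs(draws.mean() - 5) < 3 * se
        assert draws.var() == pytest.approx(5 * (1 + 2), rel=0.05)

    def test_gof_against_pmf(self):
        params = nb.NBParams(mu=5, sigma=0.4)
        draws = nb.sample_gamma_poisson(params, s_d=10, n=100_000, rng=3)
        kmax = int(np.quantile(draws, 0.999))
        obs = np.bincount(np.minimum(draws, kmax + 1))
        exp = nb.nb_pmf(np.arange(kmax + 1), mu=5, sigma=0.4) * len(draws)
        exp = np.append(exp, len(draws) - exp.sum())
        chi2 = ((obs - exp[: len(obs)]) ** 2 / exp[: len(obs)]).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.001

    def test_sigma_zero_is_poisson(self):
        draws = nb.sample_gamma_poisson(nb.NBParams(mu=4, sigma=0.0), 5, 50_000, rng=1)
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)


class TestRegression:
    def test_intercept_only_poisson_data(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(10, size=5000)
        model = nb.fit_nb_regression(np.empty((5000, 0)), y)
        assert model.beta[0] == pytest.approx(np.log(10), abs=0.05)
        assert model.sigma < 0.01
        assert model.converged

    def test_recovers_generating_coefficients(self, default_fit):
        counts, scores, model = default_fit
        beta_true = np.array([1.0, 0.5, -0.3, 0.2])
        assert np.abs(model.beta - beta_true).max() < 0.06
        assert abs(model.sigma - 0.2) < 0.05

    def test_matches_independent_optimizer(self, default_fit):
        """Cross-check against a general-purpose optimizer (Nelder-Mead)
        maximizing the same likelihood from a different start."""
        from scipy.optimize import minimize

        counts, scores, model = default_fit
        y = counts.counts("D1").astype(float)
        D = np.column_stack([np.ones(len(y)), scores])

        def negll(theta):
            mu = np.exp(np.clip(D @ theta[:-1], -700, 700))
            return -_nb_loglik(y, mu, np.exp(theta[-1]))

        res = minimize(negll, np.r_[model.beta * 0.9, np.log(0.5)],
                       method="Nelder-Mead",
                       options={"maxiter": 20000, "fatol": 1e-10, "xatol": 1e-8})
        assert model.loglik >= -res.fun - 1e-3
        assert np.abs(res.x[:-1] - model.beta).max() < 0.01

    def test_matches_statsmodels_nb2(self, default_fit):
        import statsmodels.api as sm

        counts, scores, model = default_fit
        y = counts.counts("D1")
        sm_fit = sm.NegativeBinomial(y, sm.add_constant(scores)).fit(disp=0)
        assert np.abs(sm_fit.params[:-1] - model.beta).max() < 1e-3
        assert sm_fit.params[-1] == pytest.approx(model.sigma, abs=1e-3)

    def test_nested_model_inequality(self, default_fit):
        """NB log-likelihood at the MLE dominates the Poisson solution."""
        counts, scores, model = default_fit
        y = counts.counts("D1").astype(float)
        D = np.column_stack([np.ones(len(y)), scores])
        from nbburden.nbmodel import _poisson_irls

        beta_p = _poisson_irls(D, y)
        mu_p = np.exp(D @ beta_p)
        ll_poisson_limit = _nb_loglik(y, mu_p, 1e-8)
        assert model.loglik >= ll_poisson_limit - 1e-6

    def test_coverage_of_generating_parameters(self):
        """2-SE intervals from seeded replicates cover the truth >= 90%."""
        beta_true = np.array([1.0, 0.5, -0.3, 0.2])
        hits = total = 0
        for seed in range(15):
            data = nb.simulate_dataset(nb.SyntheticConfig(), seed=100 + seed)
            counts = nb.count_mutations(data.catalog, data.bins)
            scores = data.truth["scores"][:, :3]
            model = nb.fit_nb_regression(scores, counts.counts("D1"))
            # crude SE from observed Fisher information of the mean part
            mu = model.predict_mu(scores)
            D = np.column_stack([np.ones(len(mu)), scores])
            W = mu / (1 + model.sigma * mu)
            cov = np.linalg.inv(D.T @ (D * W[:, None]))
            se = np.sqrt(np.diag(cov))
            hits += int(np.sum(np.abs(model.beta - beta_true) <= 2 * se))
            total += len(beta_true)
        assert hits / total >= 0.90

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            nb.fit_nb_regression(np.zeros((10, 1)), np.zeros(10, dtype=int))


class TestBaselines:
    def test_global_rate_mle(self):
        assert nb.fit_global_rate(100, 10**6) == pytest.approx(1e-4)
        assert nb.fit_global_rate(0, 10**6) == 0.0
        with pytest.raises(ValueError):
            nb.fit_global_rate(10, 0)

    def test_binomial_tail_enumeration(self):
        # direct enumeration of Binomial(10, 0.1) masses
        masses = [special.comb(10, k) * 0.1**k * 0.9 ** (10 - k) for k in range(3)]
        expect = 1.0 - sum(masses)
        assert nb.binomial_tail_pvalue(3, 10, 0.1) == pytest.approx(expect, rel=1e-10)
        assert round(nb.binomial_tail_pvalue(3, 10, 0.1), 4) == 0.0702

    def test_binomial_edge_cases(self):
        assert nb.binomial_tail_pvalue(0, 10, 0.1) == 1.0
        assert nb.binomial_tail_pvalue(1, 10, 0.0) == 0.0
        with pytest.raises(ValueError):
            nb.binomial_tail_pvalue(1, 10, 1.5)

    def test_law_of_rare_events(self):
        """Binomial and Poisson tails agree when n*p = lambda, p tiny."""
        n, p = 10**7, 5e-5
        lam = n * p
        for y in [1, 100, 600]:
            assert nb.binomial_tail_pvalue(y, n, p) == pytest.approx(
                nb.poisson_tail_pvalue(y, lam), abs=1e-6
            )


class TestRelativeError:
    def test_arithmetic(self):
        assert nb.relative_error([100], [100]) == 0.0
        assert nb.relative_error([100], [87.2]) == pytest.approx(0.128)
        assert nb.relative_error([50], [60]) == pytest.approx(0.2)

    def test_zero_bins_skipped(self):
        val = nb.relative_error([0, 50], [10, 60])
        assert val == pytest.approx(0.2)

    def test_median_aggregate(self):
        val = nb.relative_error([10, 10, 10], [11, 12, 20], aggregate="median")
        assert val == pytest.approx(0.2)
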