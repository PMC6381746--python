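"""Fit-level sampler tests: oracles, joint-distribution validity,
likelihood consistency, determinism."""

import numpy as np
import pytest
from scipy import stats

from bayeswin import _gibbs, models, sim
from bayeswin.models import McmcConfig, ModelSpec


def _batch_se(chain, n_batches=20):
    """Monte-Carlo standard error of a chain mean via batch means."""
    chain = np.asarray(chain)
    k = len(chain) // n_batches
    means = chain[:k * n_batches].reshape(n_batches, k).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestGaussianFit:
    def test_flat_response_gives_null_effects(self, rng):
        n, m = 80, 15
        Z = rng.integers(0, 3, size=(n, m)).astype(float)
        y = np.full(n, 3.0)
        post = models.fit(y, np.ones((n, 1)), Z,
                          ModelSpec(prior="bayesc", pi=0.05),
                          McmcConfig(n_iter=4000, burn_in=1000, thin=2, seed=2,
                                     store_effect_chains=True))
        for k in range(m):
            se = max(_batch_se(post.alpha_chain[:, k]), 1e-12)
            assert abs(post.alpha_mean[k]) < max(3 * se, 1e-6)

    def test_ridge_oracle_with_pi_one_and_fixed_variances(self, rng):
        n, m = 100, 20
        Z = rng.integers(0, 3, size=(n, m)).astype(float)
        alpha_true = rng.normal(0, 0.3, size=m)
        y = Z @ alpha_true + rng.normal(size=n)
        s2a, s2e = 0.25, 1.0
        post = models.fit(
            y, None, Z,
            ModelSpec(prior="bayesc", pi=1.0, fix_effect_var=s2a,
                      fix_resid_var=s2e),
            McmcConfig(n_iter=20_000, burn_in=2000, thin=2, seed=8,
                       store_effect_chains=True))
        ridge = np.linalg.solve(Z.T @ Z + np.eye(m) * s2e / s2a, Z.T @ y)
        for k in range(m):
            se = _batch_se(post.alpha_chain[:, k])
            assert abs(post.alpha_mean[k] - ridge[k]) < 3 * se

    def test_determinism_under_fixed_seed(self, rng):
        n, m = 60, 10
        Z = rng.integers(0, 3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        spec = ModelSpec(prior="blasso")
        mc = McmcConfig(n_iter=2000, burn_in=500, thin=2, seed=99)
        p1 = models.fit(y, None, Z, spec, mc)
        p2 = models.fit(y, None, Z, spec, mc)
        assert np.array_equal(p1.alpha_mean, p2.alpha_mean)
        assert np.array_equal(p1.sigma2_e_chain, p2.sigma2_e_chain)

    def test_divergent_variances_raise(self, rng):
        n, m = 30, 5
        Z = rng.integers(0, 3, size=(n, m)).astype(float)
        y = np.full(n, 1e200)
        y[::2] = -1e200
        with pytest.raises((RuntimeError, ValueError)):
            models.fit(y, None, Z, ModelSpec(prior="bayesc"),
                       McmcConfig(n_iter=500, burn_in=100, thin=1, seed=1))


class TestOrdinalFit:
    def test_zero_snp_probit_matches_analytic_quantile(self):
        # two categories, intercept only: the identified location is
        # cutpoint - intercept = Phi^{-1}(P(category 1))
        n, p1 = 2000, 0.3
        scores = np.ones(n, dtype=int)
        scores[int(n * p1):] = 2
        post = models.fit(scores, np.ones((n, 1)), np.empty((n, 0)),
                          ModelSpec(prior="bayesc", likelihood="ordinal",
                                    n_categories=2),
                          McmcConfig(n_iter=6000, burn_in=2000, thin=2, seed=4))
        shift = post.cutpoints_mean[0] - post.beta_mean[0]
        assert abs(shift - stats.norm.ppf(p1)) < 0.05

    def test_ordinal_matches_gaussian_fit_on_revealed_liabilities(self):
        """Binary scores with a known cutpoint carry most of the liability
        information when effects are large: the ordinal fit's marker
        estimates must track the Gaussian fit on the true liabilities."""
        cfg = sim.SimConfig(n_animals=1500, chrom_lengths_bp=(2_000_000,) * 2,
                            snps_per_chrom=(30, 30), n_qtl=12, h2=0.6,
                            genetic_variance=1.5, n_contemporary_groups=1,
                            cg_sd=0.0, age_b1=0.0, age_b2=0.0, seed=31)
        G, _ = sim.simulate_genotypes(cfg)
        alpha = sim.simulate_qtl_effects(G, cfg)
        pheno = sim.simulate_ordinal_phenotypes(G, alpha, cfg)
        liab = pheno["liability"].to_numpy()
        liab = (liab - liab.mean())
        cut = np.array([0.0])
        scores = np.where(liab <= 0.0, 1, 2)

        Z = G.astype(float)
        mc = McmcConfig(n_iter=6000, burn_in=1500, thin=2, seed=5)
        post_ord = models.fit(scores, np.ones((len(scores), 1)), Z,
                              ModelSpec(prior="bayesc", pi=0.3,
                                        likelihood="ordinal", n_categories=2,
                                        fix_cutpoints=cut), mc)
        post_gau = models.fit(liab, np.ones((len(liab), 1)), Z,
                              ModelSpec(prior="bayesc", pi=0.3,
                                        fix_resid_var=1.0), mc)
        r = np.corrcoef(post_ord.alpha_mean, post_gau.alpha_mean)[0, 1]
        assert r > 0.95

    def test_scores_outside_categories_rejected(self):
        with pytest.raises(ValueError):
            models.fit(np.array([0, 1, 2]), None, np.zeros((3, 1)),
                       ModelSpec(likelihood="ordinal"),
                       McmcConfig(n_iter=10, burn_in=1, thin=1))


class TestGewekeJointDistribution:
    """Successive-conditional simulator: alternating the Gibbs transition
    with data regeneration must leave the prior invariant. Run on a tiny
    5-SNP Gaussian instance and compare sampler marginals against direct
    prior draws (KS at alpha = 0.01)."""

    NU, SCALE = 5.0, 0.5
    N, M = 8, 5
    KEEP = 10_000

    def _prior_draws(self, rng, n_draws):
        s2e = self.NU * self.SCALE / rng.chisquare(self.NU, size=n_draws)
        s2a = self.NU * self.SCALE / rng.chisquare(self.NU, size=n_draws)
        return s2e, s2a

    def _run_chain(self, prior_tag, pi, rng):
        n, m = self.N, self.M
        Z = rng.integers(0, 3, size=(n, m)).astype(float)
        Zt = np.ascontiguousarray(Z.T)
        Xt = np.empty((0, n))
        cxx = np.empty(0)
        czz = (Zt**2).sum(axis=1)
        scores = np.zeros(n, dtype=np.int64)
        cut = np.zeros(1)
        prior = _gibbs.PRIOR_BAYESC if prior_tag == "bayesc" else _gibbs.PRIOR_BLASSO
        bl_shape, bl_rate = 1.1, 0.5

        # initial state from the prior
        s2e = self.NU * self.SCALE / rng.chisquare(self.NU)
        s2a = self.NU * self.SCALE / rng.chisquare(self.NU)
        lambda2 = rng.gamma(bl_shape, 1.0 / bl_rate)
        if prior_tag == "bayesc":
            delta = (rng.random(m) < pi).astype(np.int8)
            alpha = delta * rng.normal(0, np.sqrt(s2a), size=m)
            tau2 = np.ones(m)
        else:
            delta = np.ones(m, dtype=np.int8)
            tau2 = rng.exponential(2.0 / lambda2, size=m)
            alpha = rng.normal(0, np.sqrt(tau2 * s2e))
        beta = np.empty(0)

        _gibbs.seed_rng(int(rng.integers(2**31)))
        thin, burn = 10, 200
        out_s2e = np.empty(self.KEEP)
        out_s2a = np.empty(self.KEEP)
        out_alpha = np.empty(self.KEEP)
        kept = it = 0
        while kept < self.KEEP:
            # regenerate data given current parameters
            y = Z @ alpha + rng.normal(0, np.sqrt(s2e), size=n)
            e = y - Z @ alpha
            g = Z @ alpha
            s2a, s2e, lambda2 = _gibbs.gibbs_sweep(
                _gibbs.LIK_GAUSSIAN, prior, scores, y, Xt, cxx, Zt, czz,
                e, g, beta, alpha, delta, tau2, cut, 2,
                pi, s2a, self.NU, self.SCALE, -1.0,
                s2e, self.NU, self.SCALE, -1.0,
                lambda2, bl_shape, bl_rate, True)
            it += 1
            if it > burn and it % thin == 0:
                out_s2e[kept] = s2e
                out_s2a[kept] = s2a
                out_alpha[kept] = alpha[0]
                kept += 1
        return out_s2e, out_s2a, out_alpha

    def test_bayesc_kernel_preserves_prior(self):
        rng = np.random.default_rng(2718)
        s2e_chain, s2a_chain, alpha_chain = self._run_chain("bayesc", 0.5, rng)
        s2e_prior, s2a_prior = self._prior_draws(rng, self.KEEP)
        assert stats.ks_2samp(s2e_chain, s2e_prior).pvalue > 0.01
        assert stats.ks_2samp(s2a_chain, s2a_prior).pvalue > 0.01
        # alpha_1 prior: point mass at 0 w.p. 1-pi, else N(0, s2a)
        incl = alpha_chain != 0.0
        assert abs(incl.mean() - 0.5) < 3 * np.sqrt(0.25 / self.KEEP)
        nz = alpha_chain[incl]
        ref = s2a_prior[:len(nz)]
        prior_nz = np.random.default_rng(3141).normal(0, np.sqrt(ref))
        assert stats.ks_2samp(nz, prior_nz).pvalue > 0.01

    def test_blasso_kernel_preserves_prior(self):
        rng = np.random.default_rng(1618)
        s2e_chain, _, alpha_chain = self._run_chain("blasso", 1.0, rng)
        s2e_prior, _ = self._prior_draws(rng, self.KEEP)
        assert stats.ks_2samp(s2e_chain, s2e_prior).pvalue > 0.01
        # marginal of alpha under the hierarchy: simulate it directly
        rng2 = np.random.default_rng(577)
        lam2 = rng2.gamma(1.1, 1 / 0.5, size=self.KEEP)
        tau2 = rng2.exponential(2.0 / lam2)
        s2e_d = self.NU * self.SCALE / rng2.chisquare(self.NU, size=self.KEEP)
        alpha_prior = rng2.normal(0, np.sqrt(tau2 * s2e_d))
        assert stats.ks_2samp(alpha_chain, alpha_prior).pvalue > 0.01
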