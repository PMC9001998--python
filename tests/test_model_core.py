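"""Effect catalog, design columns and the likelihood evaluators."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, norm

from gridlong import EffectTerm, LongitudinalGridModel, ModelParams, build_effect_catalog
from gridlong.effects import EPISTATIC, MAIN, SNP_COV
from gridlong.grid import CholeskyFactors

from _oracles import reference_params, tiny_model


class TestEffectCatalog:
    @pytest.mark.parametrize(
        "p,q,d", [(3, 1, 9), (1000, 1, 501500), (2, 2, 7), (1, 1, 2)]
    )
    def test_term_count_formula(self, p, q, d):
        cat = build_effect_catalog(p, q)
        assert cat.d == d == p + p * (p - 1) // 2 + p * q

    def test_canonical_order_and_uniqueness(self):
        cat = build_effect_catalog(4, 2)
        terms = list(cat.terms())
        assert len(terms) == len(set(terms)) == cat.d
        kinds = [t.kind for t in terms]
        assert kinds == [MAIN] * 4 + [EPISTATIC] * 6 + [SNP_COV] * 8
        pairs = [(t.snp1, t.snp2) for t in terms if t.kind == EPISTATIC]
        assert pairs == sorted(pairs)
        assert all(a < b for a, b in pairs)

    def test_index_roundtrip(self):
        cat = build_effect_catalog(7, 3)
        for idx, term in enumerate(cat.terms()):
            assert cat.index_of(term) == idx

    def test_random_term_uniform(self, rng):
        cat = build_effect_catalog(5, 1)
        counts = {}
        for _ in range(4000):
            t = cat.random_term(EPISTATIC, rng)
            counts[t] = counts.get(t, 0) + 1
        assert len(counts) == cat.n_epistatic
        freqs = np.array(list(counts.values())) / 4000
        assert np.all(np.abs(freqs - 1 / 10) < 0.03)

    def test_epistatic_pair_canonicalized(self):
        assert EffectTerm(EPISTATIC, 3, 1) == EffectTerm(EPISTATIC, 1, 3)
        with pytest.raises(ValueError):
            EffectTerm(EPISTATIC, 2, 2)


class TestDesignColumns:
    def _model(self, toy_phenotypes, toy_genotypes):
        return LongitudinalGridModel(toy_phenotypes, toy_genotypes, grid=2)

    def test_product_columns(self, toy_phenotypes, toy_genotypes):
        m = self._model(toy_phenotypes, toy_genotypes)
        g1 = m.design_column(EffectTerm(MAIN, 0))
        g2 = m.design_column(EffectTerm(MAIN, 1))
        epi = m.design_column(EffectTerm(EPISTATIC, 0, 1))
        np.testing.assert_allclose(epi, g1 * g2)
        gxt = m.design_column(EffectTerm(SNP_COV, 1, cov=0))
        np.testing.assert_allclose(gxt, g2 * m.C[:, 0])

    def test_empty_active_set_is_covariates_only(self, toy_phenotypes, toy_genotypes):
        from gridlong.effects import build_design

        m = self._model(toy_phenotypes, toy_genotypes)
        X = build_design(m.G, m.subj_idx, m.C, [])
        np.testing.assert_allclose(X, m.C)

    def test_genotype_range_validated(self, toy_phenotypes, toy_genotypes):
        bad = toy_genotypes.copy()
        bad.iloc[0, 0] = 3.0
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            self._model(toy_phenotypes, bad)

    def test_missing_genotypes_mean_imputed(self, toy_phenotypes, toy_genotypes):
        g = toy_genotypes.copy()
        g.iloc[0, 0] = np.nan
        m = self._model(toy_phenotypes, g)
        assert m.G[0, 0] == g.iloc[1, 0]  # column mean of the remaining entry

    def test_extra_covariates_extend_block(self, toy_phenotypes, toy_genotypes):
        pheno = toy_phenotypes.assign(age=[3.0, 4.0, 2.0, 2.5, 3.5])
        m = LongitudinalGridModel(
            toy_phenotypes.assign(age=pheno["age"]), toy_genotypes, grid=2,
            covariates=["age"],
        )
        assert m.q == 2
        assert m.covariate_names == ["time_std", "age"]
        np.testing.assert_allclose(m.C[:, 1], pheno["age"])
        assert m.catalog.d == 2 + 1 + 2 * 2  # p + pairs + p*q

    def test_duplicate_observation_rejected(self, toy_phenotypes, toy_genotypes):
        dup = pd.concat([toy_phenotypes, toy_phenotypes.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            self._model(dup, toy_genotypes)


class TestLikelihoods:
    def test_marginal_matches_full_covariance_oracle(self):
        """Sum of per-subject MVN densities equals the density of the stacked
        N-vector with covariance P D P' + sigma^2 I."""
        m = tiny_model(seed=7, k=2)
        params = reference_params(m)
        ll = m.marginal_loglik(params)
        from gridlong.grid import build_interp_matrix, reconstruct_D

        times = [m.times_raw[m.subj_idx == i] for i in range(m.n)]
        _, P = build_interp_matrix(times, m.grid)
        D = reconstruct_D(CholeskyFactors(params.delta, params.psi))
        Dbig = np.kron(np.eye(m.n), D)
        S = P @ Dbig @ P.T + params.sigma2 * np.eye(m.N)
        mean = m.mean_vector(params)
        oracle = multivariate_normal.logpdf(m.y, mean=mean, cov=S)
        assert abs(ll - oracle) < 1e-8

    def test_marginal_equals_conditional_at_D_zero(self):
        m = tiny_model(seed=8, k=2)
        params = reference_params(m)
        params.delta = np.zeros(2)
        params.b = np.zeros((m.n, 2))
        assert abs(m.marginal_loglik(params) - m.conditional_loglik(params)) < 1e-10

    def test_marginal_invariant_to_subject_order(self):
        m = tiny_model(seed=9, k=2)
        params = reference_params(m)
        ll = m.marginal_loglik(params)
        # rebuild with subjects relabelled in reverse order
        pheno = m.pheno_frame.copy()
        pheno["subject_id"] = pheno["subject_id"].map(lambda s: f"z{9 - int(s[1:])}")
        geno = pd.DataFrame(
            m.G[::-1], index=[f"z{9 - i}" for i in range(m.n)][::-1],
            columns=[f"g{j}" for j in range(m.p)],
        )
        m2 = LongitudinalGridModel(pheno, geno, grid=m.grid)
        b_perm = params.b[::-1]
        p2 = ModelParams(
            mu=params.mu, sigma2=params.sigma2, delta=params.delta, psi=params.psi,
            beta_cov=params.beta_cov, active=params.active, b=b_perm,
        )
        assert abs(m2.marginal_loglik(p2) - ll) < 1e-8

    def test_conditional_reduces_to_univariate_sum(self):
        m = tiny_model(seed=10, k=2)
        params = reference_params(m)
        resid = m.y - m.mean_vector(params) - m.random_effect_values(params)
        oracle = norm.logpdf(resid, scale=np.sqrt(params.sigma2)).sum()
        assert abs(m.conditional_loglik(params) - oracle) < 1e-10

    def test_vi_product_identity(self):
        """v_i v_i' = p_i D p_i' for every subject."""
        m = tiny_model(seed=11, k=3)
        params = reference_params(m)
        fac = CholeskyFactors(params.delta, params.psi)
        from gridlong.grid import reconstruct_D

        D = reconstruct_D(fac)
        for i in range(m.n):
            pi = m.W[m.subj_idx == i]
            vi = pi @ fac.L()
            np.testing.assert_allclose(vi @ vi.T, pi @ D @ pi.T, atol=1e-10)

    def test_monte_carlo_marginalization(self, rng):
        """Averaging exp(conditional log-lik) over b ~ N(0, I) recovers the
        marginal likelihood within Monte Carlo error."""
        m = tiny_model(seed=12, k=2, n=3)
        params = reference_params(m)
        target = m.marginal_loglik(params)
        M = 200_000
        lls = np.empty(M)
        bdraws = rng.standard_normal((M, m.n, 2))
        fac = CholeskyFactors(params.delta, params.psi)
        L = fac.L()
        mean = m.mean_vector(params)
        base_resid = m.y - mean
        for j in range(M):
            re = np.einsum("ok,ok->o", m.W, (bdraws[j] @ L.T)[m.subj_idx])
            r = base_resid - re
            lls[j] = -0.5 * (
                m.N * np.log(2 * np.pi * params.sigma2) + r @ r / params.sigma2
            )
        est = logsumexp(lls) - np.log(M)
        w = np.exp(lls - lls.max())
        se = np.std(w, ddof=1) / (np.mean(w) * np.sqrt(M))  # relative SE of the mean
        assert abs(est - target) < 3 * se

    def test_sigma2_zero_pseudo_determinant(self):
        """With sigma^2 = 0 and all subjects on the grid the marginal density
        is the nonsingular N(mean, D) density; off-space residuals get -inf."""
        rng = np.random.default_rng(0)
        k = 2
        pheno = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "time": [0.0, 1.0, 0.0, 1.0],
                "value": rng.normal(size=4),
            }
        )
        geno = pd.DataFrame(
            {"g1": [0.0, 1.0]}, index=pd.Index(["a", "b"], name="subject_id")
        )
        m = LongitudinalGridModel(pheno, geno, grid=[0.0, 1.0])
        params = ModelParams(
            mu=0.0, sigma2=0.0, delta=np.array([1.0, 0.8]), psi=np.array([0.5]),
            beta_cov=np.zeros(1), active=[], b=np.zeros((2, k)),
        )
        from gridlong.grid import reconstruct_D

        D = reconstruct_D(CholeskyFactors(params.delta, params.psi))
        oracle = sum(
            multivariate_normal.logpdf(m.y[m.subj_idx == i], mean=np.zeros(2), cov=D)
            for i in range(2)
        )
        assert abs(m.marginal_loglik(params) - oracle) < 1e-8
        # rank-deficient D with residual outside its column space -> -inf
        params.delta = np.array([1.0, 0.0])
        params.psi = np.array([0.0])
        assert m.marginal_loglik(params) == float("-inf")
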