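"""Correctness of the Gibbs full conditionals.

Every conjugate update is checked against an independent numerical oracle:
the conditional density of one coordinate is proportional to the model's
conditional likelihood (evaluated through the likelihood interface, not the
sampler's algebra) times that coordinate's prior, integrated on a fine grid.
Draws produced by the sampler's conditional parameters must match the grid
CDF in Kolmogorov-Smirnov distance.  A successive-conditional simulation
(alternately drawing data given parameters and parameters given data) then
verifies that the full sweep leaves the prior invariant.
"""

import math

import numpy as np
import pytest
from scipy.stats import invgamma, norm

from gridlong import GibbsSampler, McmcConfig, ModelParams
from gridlong.effects import EffectTerm
from gridlong.sampler import _truncnorm_pos

from _oracles import grid_cdf, ks_distance, make_sampler, reference_params, tiny_model

M_DRAWS = 20_000
KS_TOL = 0.02  # ~2.2 / sqrt(M_DRAWS)


def _halfnormal_logpdf(x, m0, s02):
    return norm.logpdf(x, loc=m0, scale=math.sqrt(s02))  # + const (truncation)


def _invchi2_logpdf(x, nu, s2):
    return invgamma.logpdf(x, a=nu / 2.0, scale=nu * s2 / 2.0)


@pytest.fixture
def sampler_state():
    model = tiny_model(seed=5, k=2)
    s = make_sampler(model)
    s.set_params(reference_params(model))
    return model, s


def _modified(params, **kw):
    import copy

    p = copy.deepcopy(params)
    for key, val in kw.items():
        setattr(p, key, val)
    return p


class TestClosedForms:
    def test_b_prior_when_no_loading(self):
        """A subject whose interpolation rows are all zero on delta (delta=0)
        contributes no likelihood information: conditional of b is the prior."""
        model = tiny_model(seed=5, k=2)
        s = make_sampler(model)
        p = reference_params(model)
        p.delta = np.zeros(2)
        s.set_params(p)
        mean, prec = s.b_conditional()
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(prec, np.broadcast_to(np.eye(2), prec.shape))

    def test_delta_prior_when_no_loading(self):
        model = tiny_model(seed=5, k=2)
        s = make_sampler(model)
        p = reference_params(model)
        p.b = np.zeros((model.n, 2))  # coefficient a_ijl (Psi b)_l vanishes
        s.set_params(p)
        mean, sd = s.delta_conditional(0)
        assert abs(mean - s.priors.delta_m0) < 1e-12
        assert abs(sd - math.sqrt(s.priors.delta_s02)) < 1e-12

    def test_psi_prior_when_delta_zero(self):
        model = tiny_model(seed=5, k=2)
        s = make_sampler(model)
        p = reference_params(model)
        p.delta = np.zeros(2)
        s.set_params(p)
        mean, prec = s.psi_conditional()
        np.testing.assert_allclose(mean, s.priors.psi_mean, atol=1e-12)
        np.testing.assert_allclose(prec, np.eye(1) / s.priors.psi_var)

    def test_scalar_normal_normal_update(self, sampler_state):
        """The b conditional in the scalar case matches the textbook
        normal-normal posterior computed directly in the test."""
        model, s = sampler_state
        mean, prec = s.b_conditional()
        L = s.delta[:, None] * s.Psi
        for i in range(model.n):
            rows = model.subj_idx == i
            vi = model.W[rows] @ L
            ri = (s.resid + s.re)[rows]
            prec_o = np.eye(2) + vi.T @ vi / s.sigma2
            mean_o = np.linalg.solve(prec_o, vi.T @ ri / s.sigma2)
            np.testing.assert_allclose(prec[i], prec_o, atol=1e-10)
            np.testing.assert_allclose(mean[i], mean_o, atol=1e-10)

    def test_sigma_beta2_draw_with_zero_beta(self):
        """beta_a = 0 reduces the sigma_beta^2 conditional to
        Inv-chi2(nu+1, nu s^2 / (nu+1)); check against direct quantiles."""
        model = tiny_model(seed=5, k=2)
        s = make_sampler(model, seed=11)
        p = reference_params(model)
        p.active = [(EffectTerm("main", 0), 0.0)]
        s.set_params(p)
        nu = s.priors.nu_beta
        s2 = s.active[0].s2
        draws = np.empty(5000)
        for j in range(5000):
            s.update_sigma_beta2()
            draws[j] = s.active[0].sigma_b2
        # scaled-inv-chi2(nu+1, nu*s2/(nu+1)) quantile comparison
        ref = invgamma(a=(nu + 1) / 2.0, scale=nu * s2 / 2.0)
        qs = np.quantile(draws, [0.1, 0.5, 0.9])
        np.testing.assert_allclose(qs, ref.ppf([0.1, 0.5, 0.9]), rtol=0.1)

    def test_mu_posterior_no_effects(self):
        """With no genetic effects and no random effects the mu conditional is
        the standard normal-normal combination of prior and N data points."""
        model = tiny_model(seed=5, k=2)
        s = make_sampler(model)
        p = reference_params(model)
        p.active = []
        p.beta_cov = np.zeros(model.q)
        p.delta = np.zeros(2)
        p.b = np.zeros((model.n, 2))
        s.set_params(p)
        mean, sd = s.mu_conditional()
        pr = s.priors
        prec_o = 1 / pr.tau02 + model.N / s.sigma2
        mean_o = (pr.eta0 / pr.tau02 + model.y.sum() / s.sigma2) / prec_o
        assert abs(mean - mean_o) < 1e-10
        assert abs(sd - prec_o**-0.5) < 1e-12


class TestGridOracles:
    """KS agreement between conditional draws and grid-integrated densities."""

    def test_delta_conditional(self, sampler_state, rng):
        model, s = sampler_state
        params = s.params()
        mean, sd = s.delta_conditional(0)
        draws = np.array([_truncnorm_pos(mean, sd, rng) for _ in range(M_DRAWS)])
        xs = np.linspace(0.0, mean + 8 * sd, 3001)
        pr = s.priors
        logd = np.array(
            [
                model.conditional_loglik(_modified(params, delta=np.array([x, params.delta[1]])))
                + _halfnormal_logpdf(x, pr.delta_m0, pr.delta_s02)
                for x in xs
            ]
        )
        assert ks_distance(draws, xs, grid_cdf(xs, logd)) < KS_TOL

    def test_psi_conditional(self, sampler_state, rng):
        model, s = sampler_state
        params = s.params()
        mean, prec = s.psi_conditional()
        sd = 1.0 / math.sqrt(prec[0, 0])
        draws = mean[0] + sd * rng.standard_normal(M_DRAWS)
        xs = np.linspace(mean[0] - 8 * sd, mean[0] + 8 * sd, 3001)
        pr = s.priors
        logd = np.array(
            [
                model.conditional_loglik(_modified(params, psi=np.array([x])))
                + norm.logpdf(x, pr.psi_mean, math.sqrt(pr.psi_var))
                for x in xs
            ]
        )
        assert ks_distance(draws, xs, grid_cdf(xs, logd)) < KS_TOL

    def test_b_conditional_coordinates(self, sampler_state, rng):
        """Subject 0's joint b draw matches a 2-D mesh oracle coordinatewise."""
        model, s = sampler_state
        mean, prec = s.b_conditional()
        Lc = np.linalg.cholesky(prec[0])
        z = rng.standard_normal((M_DRAWS, 2))
        draws = mean[0] + np.linalg.solve(Lc.T, z.T).T
        # mesh oracle from subject 0's own observations
        rows = model.subj_idx == 0
        L = s.delta[:, None] * s.Psi
        vi = model.W[rows] @ L
        ri = (s.resid + s.re)[rows]
        g1 = np.linspace(mean[0, 0] - 6, mean[0, 0] + 6, 401)
        g2 = np.linspace(mean[0, 1] - 6, mean[0, 1] + 6, 401)
        B1, B2 = np.meshgrid(g1, g2, indexing="ij")
        fit = vi[:, 0] * B1[..., None] + vi[:, 1] * B2[..., None]
        logd = (
            -0.5 * ((ri - fit) ** 2).sum(-1) / s.sigma2
            - 0.5 * (B1**2 + B2**2)
        )
        dens = np.exp(logd - logd.max())
        for axis, grid_ax in ((1, g1), (0, g2)):
            marg = dens.sum(axis=axis)
            cdf = np.cumsum(marg)
            cdf /= cdf[-1]
            d = ks_distance(draws[:, 1 - axis], grid_ax, cdf)
            assert d < KS_TOL + 0.01  # mesh-discretization slack

    def test_mu_conditional(self, sampler_state, rng):
        model, s = sampler_state
        params = s.params()
        mean, sd = s.mu_conditional()
        draws = mean + sd * rng.standard_normal(M_DRAWS)
        xs = np.linspace(mean - 8 * sd, mean + 8 * sd, 3001)
        pr = s.priors
        logd = np.array(
            [
                model.conditional_loglik(_modified(params, mu=x))
                + norm.logpdf(x, pr.eta0, math.sqrt(pr.tau02))
                for x in xs
            ]
        )
        assert ks_distance(draws, xs, grid_cdf(xs, logd)) < KS_TOL

    def test_sigma2_conditional(self, sampler_state, rng):
        model, s = sampler_state
        params = s.params()
        dof, scale = s.sigma2_conditional()
        draws = dof * scale / rng.chisquare(dof, M_DRAWS)
        lo, hi = np.quantile(draws, [0.0001, 0.9999])
        xs = np.linspace(0.5 * lo, 1.5 * hi, 3001)
        pr = s.priors
        logd = np.array(
            [
                model.conditional_loglik(_modified(params, sigma2=x))
                + _invchi2_logpdf(x, pr.nu_sigma, pr.s_sigma2)
                for x in xs
            ]
        )
        assert ks_distance(draws, xs, grid_cdf(xs, logd)) < KS_TOL

    def test_beta_conditional(self, sampler_state, rng):
        model, s = sampler_state
        params = s.params()
        mean, sd = s.beta_conditional(0)
        draws = mean + sd * rng.standard_normal(M_DRAWS)
        xs = np.linspace(mean - 8 * sd, mean + 8 * sd, 3001)
        sb2 = s.active[0].sigma_b2
        term = s.active[0].term
        logd = np.array(
            [
                model.conditional_loglik(_modified(params, active=[(term, x)]))
                + norm.logpdf(x, 0.0, math.sqrt(sb2))
                for x in xs
            ]
        )
        assert ks_distance(draws, xs, grid_cdf(xs, logd)) < KS_TOL


class TestTruncatedNormalSampler:
    @pytest.mark.parametrize("mean,sd", [(0.5, 1.0), (-2.0, 0.5), (-8.0, 1.0)])
    def test_matches_scipy_truncnorm(self, mean, sd, rng):
        from scipy.stats import kstest, truncnorm

        draws = np.array([_truncnorm_pos(mean, sd, rng) for _ in range(10_000)])
        assert np.all(draws >= 0)
        a = (0.0 - mean) / sd
        stat = kstest(draws, truncnorm(a, np.inf, loc=mean, scale=sd).cdf).statistic
        assert stat < 0.02


class TestSuccessiveConditional:
    def test_sweep_preserves_prior(self):
        """Alternating theta -> y -> theta with the full Gibbs sweep is a
        Markov chain whose stationary law is the prior; parameter means must
        match their prior expectations (ESS-corrected |Z| < 4)."""
        import arviz as az

        model = tiny_model(seed=21, k=2, n=10)
        priors = model.priors.replace(
            delta_s02=1.5,
            tau02=1.0,
            eta0=0.5,
            s_sigma2=1.0,
            nu_sigma=8.0,
            psi_var=0.5,
            cov_effect_var=1.0,
        )
        model.priors = priors
        cfg = McmcConfig(
            seed=0,
            update=("beta", "beta_cov", "sigma_beta2", "b", "delta", "psi", "mu", "sigma2"),
        )
        s = GibbsSampler(model, priors, cfg)
        s.set_params(
            ModelParams(
                mu=priors.eta0,
                sigma2=1.0,
                delta=np.full(2, 0.5),
                psi=np.zeros(1),
                beta_cov=np.zeros(model.q),
                active=[(EffectTerm("main", 0), 0.0)],
                b=np.zeros((model.n, 2)),
            )
        )
        data_rng = np.random.default_rng(99)
        M = 6000
        rec = {k: np.empty(M) for k in ("mu", "sigma2", "delta1", "delta2", "psi", "beta", "bcov")}
        for t in range(M):
            mean = s._fixed_mean() + s.re
            s.y[:] = mean + data_rng.normal(0.0, math.sqrt(s.sigma2), model.N)
            s.resid = s.y - mean
            s.sweep()
            rec["mu"][t] = s.mu
            rec["sigma2"][t] = s.sigma2
            rec["delta1"][t] = s.delta[0]
            rec["delta2"][t] = s.delta[1]
            rec["psi"][t] = s.psi[0]
            rec["beta"][t] = s.active[0].beta
            rec["bcov"][t] = s.beta_cov[0]
        nu = priors.nu_sigma
        expected = {
            "mu": priors.eta0,
            "sigma2": nu * priors.s_sigma2 / (nu - 2),
            "delta1": math.sqrt(2 * priors.delta_s02 / math.pi),
            "delta2": math.sqrt(2 * priors.delta_s02 / math.pi),
            "psi": priors.psi_mean,
            "beta": 0.0,
            "bcov": 0.0,
        }
        for name, tr in rec.items():
            ess = max(float(az.ess(tr)), 10.0)
            se = tr.std(ddof=1) / math.sqrt(ess)
            z = (tr.mean() - expected[name]) / se
            assert abs(z) < 4.0, f"{name}: mean {tr.mean():.3f} vs {expected[name]:.3f}, Z={z:.2f}"
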