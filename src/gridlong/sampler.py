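"""Metropolis-Hastings-within-Gibbs sampler for the grid-based mixed model.

The joint posterior factorizes as

    P(gamma, theta | y) prop. P(y|gamma, theta) P(gamma) P(lambda) P(beta|gamma)
                              P(b) P(delta) P(psi) P(mu) P(sigma^2),

and is explored by alternating (i) Metropolis-Hastings moves on the composite
model space (which effects are active and at which SNP positions) and
(ii) conjugate Gibbs draws for everything else.  All continuous full
conditionals follow from normal / half-normal / scaled-inverse-chi-square
conjugacy:

* ``b_i``: multivariate normal, precision ``I_k + v_i' v_i / sigma^2`` with
  ``v_i = p_i Delta Psi``;
* ``delta_l``: half-normal times normal likelihood, a positive truncated
  normal (the observation-level coefficient of ``delta_l`` is
  ``a_ijl (Psi b_i)_l``);
* ``psi``: joint multivariate normal (coefficient of ``psi_ml`` is
  ``a_ijm delta_m b_il``);
* ``beta_a``, covariate effects and ``mu``: scalar normal-normal updates;
* ``sigma_beta_a^2``: Inv-chi2(nu_beta + 1, (beta_a^2 + nu_beta s_beta_a^2) /
  (nu_beta + 1));
* ``sigma^2``: Inv-chi2(nu_sigma + N, (nu_sigma s_sigma^2 + RSS) /
  (nu_sigma + N)) with the conditional residual sum of squares RSS.

The model-space move set per sweep is one of {add, delete, move-position,
beta refresh} with probabilities (0.3, 0.3, 0.2, 0.2); an add proposes the
effect type proportional to its prior mass, the term uniformly within type,
and ``(sigma_beta^2, beta)`` from their priors, so those prior terms cancel
in the acceptance ratio.  A configurable cap bounds the number of
simultaneously active effects (composite-model-space formulation).

When ``sigma^2`` is frozen at zero (the non-identifiability escape) the
explicit-``b`` sweep degenerates, so the sampler switches to a collapsed
variant: ``b`` is integrated out analytically and ``mu``, the covariate
effects, ``delta``, ``psi`` and the model space are updated by random-walk /
prior-proposal Metropolis steps on the singular marginal likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .effects import EPISTATIC, MAIN, SNP_COV, EffectTerm
from .grid import psi_matrix, psi_vector
from .model import LongitudinalGridModel, ModelParams
from .priors import PriorSpec, s_beta2

__all__ = ["McmcConfig", "ChainResult", "run_mcmc", "GibbsSampler"]

_ALL_UPDATES = (
    "gamma",
    "beta",
    "beta_cov",
    "sigma_beta2",
    "b",
    "delta",
    "psi",
    "mu",
    "sigma2",
)


@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule and sampler options.

    The default analysis schedule is 4x10^5 iterations after 1,000 burn-in
    sweeps, thinned every 40, yielding 10^4 retained samples.  Shorter chains
    need proportionally longer burn-ins (see the methods note).
    """

    n_iter: int = 400_000
    burn_in: int = 1000
    thin: int = 40
    seed: int = 0
    move_probs: tuple = (0.3, 0.3, 0.2, 0.2)  # add, delete, move, refresh
    mh_moves_per_sweep: int = 1
    max_active: Optional[int] = None
    fix_sigma2: bool = False
    fixed_sigma_beta2: Optional[float] = None
    update: tuple = _ALL_UPDATES
    store_b: bool = False
    rw_scale: float = 0.25  # collapsed-sampler random-walk scale factor

    def replace(self, **kw) -> "McmcConfig":
        return replace(self, **kw)

    @property
    def n_samples(self) -> int:
        return self.n_iter // self.thin


@dataclass
class ChainResult:
    """Thinned posterior samples plus what DIC/BPIC and summaries need."""

    mu: np.ndarray
    sigma2: np.ndarray
    delta: np.ndarray  # T x k
    psi: np.ndarray  # T x k(k-1)/2
    beta_cov: np.ndarray  # T x q
    loglik: np.ndarray  # per-sample marginal log P(y | gamma, theta)
    actives: list  # per sample: [(EffectTerm, beta), ...]
    mean_fitted: np.ndarray  # posterior mean of mu + x Gamma beta (length N)
    n_active: np.ndarray
    p: int
    q: int
    config: McmcConfig = None
    priors: PriorSpec = None
    b: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return self.mu.size

    def snp_hits(self, kinds: Optional[tuple] = None) -> np.ndarray:
        """T x p boolean: sample t involves SNP j through any active effect
        (optionally restricted to the given effect kinds)."""
        hits = np.zeros((self.n_samples, self.p), dtype=bool)
        for t, snap in enumerate(self.actives):
            for term, _beta in snap:
                if kinds is None or term.kind in kinds:
                    for s in term.snps:
                        hits[t, s] = True
        return hits


class _ActiveEffect:
    __slots__ = ("term", "beta", "sigma_b2", "s2", "col", "col_ss")

    def __init__(self, term, beta, sigma_b2, s2, col):
        self.term = term
        self.beta = beta
        self.sigma_b2 = sigma_b2
        self.s2 = s2
        self.col = col
        self.col_ss = float(col @ col)


def _truncnorm_pos(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Draw from N(mean, sd^2) truncated to [0, inf) (inverse CDF with a
    Robert-style exponential-rejection fallback deep in the tail)."""
    a = -mean / sd
    Fa = ndtr(a)
    if Fa < 1.0 - 1e-10:
        u = rng.uniform()
        return mean + sd * float(ndtri(Fa + u * (1.0 - Fa)))
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a + rng.exponential(1.0 / alpha)
        if rng.uniform() <= math.exp(-0.5 * (z - alpha) ** 2):
            return mean + sd * z


def _log_invchi2(x: float, nu: float, s2: float) -> float:
    """Log density of the scaled inverse chi-square distribution."""
    h = 0.5 * nu
    return (
        h * math.log(h * s2)
        - math.lgamma(h)
        - (h + 1.0) * math.log(x)
        - nu * s2 / (2.0 * x)
    )


class GibbsSampler:
    """Stateful sampler; tests drive individual updates, :func:`run_mcmc`
    drives full chains."""

    def __init__(
        self, model: LongitudinalGridModel, priors: PriorSpec, config: McmcConfig
    ):
        self.model = model
        self.priors = priors
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.k = model.k
        self.n_psi = self.k * (self.k - 1) // 2
        self.subj_idx = model.subj_idx
        self.W = model.W
        self.y = model.y
        self.C = model.C
        self.N = model.N

        cat = model.catalog
        mass = np.array(
            [
                priors.w_main * cat.n_main,
                priors.w_epistatic * cat.n_epistatic,
                priors.w_snp_cov * cat.n_snp_cov,
            ]
        )
        self._kind_probs = mass / mass.sum()
        self._kinds = (MAIN, EPISTATIC, SNP_COV)
        exp_active = priors.expected_active(cat)
        self.max_active = (
            config.max_active
            if config.max_active is not None
            else max(3, int(math.ceil(3.0 * exp_active)))
        )
        self._s2_cache: dict = {}
        self._cov_ss = np.einsum("oj,oj->j", self.C, self.C)

        # --- initial state -------------------------------------------------
        self.mu = float(np.mean(self.y))
        self.sigma2 = 0.0 if config.fix_sigma2 else float(np.var(self.y, ddof=1)) / 2.0
        self.beta_cov = np.zeros(model.q)
        self.active: list[_ActiveEffect] = []
        self._active_keys: set = set()
        if model.random_effects:
            self.delta = np.full(self.k, 0.5)
        else:
            self.delta = np.zeros(self.k)
        self.psi = np.zeros(self.n_psi)
        self.Psi = psi_matrix(self.psi, self.k)
        self.b = np.zeros((model.n, self.k))
        self.re = np.zeros(self.N)
        self.resid = self.y - self.mu - self.re
        self._collapsed = config.fix_sigma2
        if self._collapsed:
            self._ll = self._marginal_ll()

    # ------------------------------------------------------------------ #
    # state plumbing

    def params(self) -> ModelParams:
        return ModelParams(
            mu=self.mu,
            sigma2=self.sigma2,
            delta=self.delta.copy(),
            psi=self.psi.copy(),
            beta_cov=self.beta_cov.copy(),
            active=[(e.term, e.beta) for e in self.active],
            b=self.b.copy(),
        )

    def set_params(self, params: ModelParams) -> None:
        self.mu = float(params.mu)
        self.sigma2 = float(params.sigma2)
        self.delta = np.asarray(params.delta, dtype=float).copy()
        self.psi = np.asarray(params.psi, dtype=float).copy()
        self.Psi = psi_matrix(self.psi, self.k)
        self.beta_cov = np.asarray(params.beta_cov, dtype=float).copy()
        if params.b is not None:
            self.b = np.asarray(params.b, dtype=float).copy()
        self.active = []
        self._active_keys = set()
        for term, beta in params.active:
            col = self.model.design_column(term)
            s2 = self._s_beta2(term, col)
            sb2 = (
                self.config.fixed_sigma_beta2
                if self.config.fixed_sigma_beta2 is not None
                else self.priors.nu_beta * s2 / max(self.priors.nu_beta - 2.0, 1.0)
            )
            self.active.append(_ActiveEffect(term, float(beta), sb2, s2, col))
            self._active_keys.add(term)
        self._refresh_re()
        if self._collapsed:
            self._ll = self._marginal_ll()

    def _fixed_mean(self) -> np.ndarray:
        mean = self.mu + self.C @ self.beta_cov
        for e in self.active:
            mean = mean + e.beta * e.col
        return mean

    def _refresh_re(self) -> None:
        if self.model.random_effects:
            u = self.b @ self.Psi.T
            du = self.delta * u
            self.re = np.einsum("ok,ok->o", self.W, du[self.subj_idx])
        else:
            self.re = np.zeros(self.N)
        self.resid = self.y - self._fixed_mean() - self.re

    def _s_beta2(self, term: EffectTerm, col: np.ndarray) -> float:
        s2 = self._s2_cache.get(term)
        if s2 is None:
            s2 = s_beta2(self.priors, float(np.var(col, ddof=1)))
            self._s2_cache[term] = s2
        return s2

    def _marginal_ll(self) -> float:
        return self.model.marginal_loglik_from_mean(
            self._fixed_mean(), self.delta, self.psi, self.sigma2
        )

    # ------------------------------------------------------------------ #
    # conjugate full-conditional parameters (pure; used by updates and tests)

    def b_conditional(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean (n x k) and precision (n x k x k) of all b_i."""
        L = self.delta[:, None] * self.Psi
        V = self.model.W_pad @ L
        rb = np.append(self.resid + self.re, 0.0)[self.model.pad_idx]
        prec = np.einsum("nmk,nml->nkl", V, V) / self.sigma2
        prec[:, np.arange(self.k), np.arange(self.k)] += 1.0
        rhs = np.einsum("nmk,nm->nk", V, rb) / self.sigma2
        mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
        return mean, prec

    def delta_conditional(self, l: int) -> tuple[float, float]:
        """(mean, sd) of the untruncated normal whose positive part is the
        full conditional of delta_l."""
        pr = self.priors
        u = self.b @ self.Psi.T
        c = self.W[:, l] * u[self.subj_idx, l]
        rho = self.resid + self.delta[l] * c
        prec = 1.0 / pr.delta_s02 + float(c @ c) / self.sigma2
        mean = (pr.delta_m0 / pr.delta_s02 + float(c @ rho) / self.sigma2) / prec
        return mean, 1.0 / math.sqrt(prec)

    def psi_conditional(self) -> tuple[np.ndarray, np.ndarray]:
        """(mean, precision) of the joint normal full conditional of psi."""
        pr = self.priors
        Wd = self.W * self.delta
        bs = self.b[self.subj_idx]
        cols = [Wd[:, m] * bs[:, l] for m in range(1, self.k) for l in range(m)]
        G = np.column_stack(cols)
        base = np.einsum("ok,ok->o", Wd, bs)
        rho = self.resid + self.re - base
        prec = np.eye(self.n_psi) / pr.psi_var + (G.T @ G) / self.sigma2
        rhs = np.full(self.n_psi, pr.psi_mean / pr.psi_var) + (G.T @ rho) / self.sigma2
        mean = np.linalg.solve(prec, rhs)
        return mean, prec

    def mu_conditional(self) -> tuple[float, float]:
        pr = self.priors
        rho = self.resid + self.mu
        prec = 1.0 / pr.tau02 + self.N / self.sigma2
        mean = (pr.eta0 / pr.tau02 + float(np.sum(rho)) / self.sigma2) / prec
        return mean, 1.0 / math.sqrt(prec)

    def sigma2_conditional(self) -> tuple[float, float]:
        """(dof, scale) of the scaled-inv-chi2 full conditional: the draw is
        dof * scale / chi2(dof)."""
        pr = self.priors
        rss = float(self.resid @ self.resid)
        dof = pr.nu_sigma + self.N
        return dof, (pr.nu_sigma * pr.s_sigma2 + rss) / dof

    def beta_conditional(self, j: int) -> tuple[float, float]:
        e = self.active[j]
        rho_x = float(e.col @ self.resid) + e.beta * e.col_ss
        prec = 1.0 / e.sigma_b2 + e.col_ss / self.sigma2
        mean = (rho_x / self.sigma2) / prec
        return mean, 1.0 / math.sqrt(prec)

    # ------------------------------------------------------------------ #
    # Gibbs updates

    def update_b(self) -> None:
        mean, prec = self.b_conditional()
        Lc = np.linalg.cholesky(prec)
        z = self.rng.standard_normal((self.model.n, self.k))
        self.b = mean + np.linalg.solve(Lc.transpose(0, 2, 1), z[..., None])[..., 0]
        rb = self.resid + self.re
        u = self.b @ self.Psi.T
        du = self.delta * u
        self.re = np.einsum("ok,ok->o", self.W, du[self.subj_idx])
        self.resid = rb - self.re

    def update_delta(self) -> None:
        u = self.b @ self.Psi.T
        coef = self.W * u[self.subj_idx]
        pr = self.priors
        for l in range(self.k):
            c = coef[:, l]
            rho = self.resid + self.delta[l] * c
            prec = 1.0 / pr.delta_s02 + float(c @ c) / self.sigma2
            mean = (pr.delta_m0 / pr.delta_s02 + float(c @ rho) / self.sigma2) / prec
            new = _truncnorm_pos(mean, 1.0 / math.sqrt(prec), self.rng)
            self.resid = rho - new * c
            self.delta[l] = new
        self.re = coef @ self.delta

    def update_psi(self) -> None:
        if self.n_psi == 0:
            return
        mean, prec = self.psi_conditional()
        Lc = np.linalg.cholesky(prec)
        z = self.rng.standard_normal(self.n_psi)
        new = mean + np.linalg.solve(Lc.T, z)
        rho_full = self.resid + self.re
        self.psi = new
        self.Psi = psi_matrix(self.psi, self.k)
        u = self.b @ self.Psi.T
        du = self.delta * u
        self.re = np.einsum("ok,ok->o", self.W, du[self.subj_idx])
        self.resid = rho_full - self.re

    def update_mu(self) -> None:
        mean, sd = self.mu_conditional()
        rho = self.resid + self.mu
        self.mu = mean + sd * self.rng.standard_normal()
        self.resid = rho - self.mu

    def update_sigma2(self) -> None:
        if self.config.fix_sigma2:
            return
        dof, scale = self.sigma2_conditional()
        self.sigma2 = dof * scale / self.rng.chisquare(dof)

    def update_beta_cov(self) -> None:
        pr = self.priors
        for j in range(self.model.q):
            x = self.C[:, j]
            rho = self.resid + self.beta_cov[j] * x
            prec = 1.0 / pr.cov_effect_var + self._cov_ss[j] / self.sigma2
            mean = (float(x @ rho) / self.sigma2) / prec
            new = mean + self.rng.standard_normal() / math.sqrt(prec)
            self.resid = rho - new * x
            self.beta_cov[j] = new

    def update_active_betas(self) -> None:
        for j in range(len(self.active)):
            self._gibbs_beta(j)

    def _gibbs_beta(self, j: int) -> None:
        e = self.active[j]
        mean, sd = self.beta_conditional(j)
        new = mean + sd * self.rng.standard_normal()
        self.resid = self.resid + (e.beta - new) * e.col
        e.beta = new

    def update_sigma_beta2(self) -> None:
        if self.config.fixed_sigma_beta2 is not None:
            for e in self.active:
                e.sigma_b2 = self.config.fixed_sigma_beta2
            return
        nu = self.priors.nu_beta
        for e in self.active:
            scale = e.beta**2 + nu * e.s2
            e.sigma_b2 = scale / self.rng.chisquare(nu + 1.0)

    # ------------------------------------------------------------------ #
    # model-space Metropolis-Hastings

    def _draw_sigma_b2_prior(self, s2: float) -> float:
        if self.config.fixed_sigma_beta2 is not None:
            return self.config.fixed_sigma_beta2
        nu = self.priors.nu_beta
        return nu * s2 / self.rng.chisquare(nu)

    def _loglik_delta_from_resid(self, resid_new: np.ndarray) -> float:
        if self._collapsed:
            raise RuntimeError("use collapsed path")
        rss_old = float(self.resid @ self.resid)
        rss_new = float(resid_new @ resid_new)
        return (rss_old - rss_new) / (2.0 * self.sigma2)

    def mh_move(self) -> None:
        u = self.rng.uniform()
        p_add, p_del, p_move, _p_ref = self.config.move_probs
        if u < p_add:
            self._move_add()
        elif u < p_add + p_del:
            self._move_delete()
        elif u < p_add + p_del + p_move:
            self._move_position()
        else:
            self._move_refresh()

    def _pick_kind(self) -> str:
        u = self.rng.uniform()
        cum = 0.0
        for kind, pk in zip(self._kinds, self._kind_probs):
            cum += pk
            if u < cum:
                return kind
        return self._kinds[-1]

    def _move_add(self) -> None:
        if len(self.active) >= self.max_active:
            return
        kind = self._pick_kind()
        term = self.model.catalog.random_term(kind, self.rng)
        if term in self._active_keys:
            return
        col = self.model.design_column(term)
        s2 = self._s_beta2(term, col)
        sigma_b2 = self._draw_sigma_b2_prior(s2)
        beta = self.rng.normal(0.0, math.sqrt(sigma_b2))
        w = self.priors.w(kind)
        p_add, p_del = self.config.move_probs[0], self.config.move_probs[1]
        kind_i = self._kinds.index(kind)
        log_q_add = (
            math.log(p_add)
            + math.log(self._kind_probs[kind_i])
            - math.log(self.model.catalog.count(kind))
        )
        log_q_del = math.log(p_del) - math.log(len(self.active) + 1)
        if self._collapsed:
            e = _ActiveEffect(term, beta, sigma_b2, s2, col)
            self.active.append(e)
            ll_new = self._marginal_ll()
            dll = ll_new - self._ll
            self.active.pop()
        else:
            resid_new = self.resid - beta * col
            dll = self._loglik_delta_from_resid(resid_new)
        log_r = dll + math.log(w / (1.0 - w)) + log_q_del - log_q_add
        if math.log(self.rng.uniform()) < log_r:
            self.active.append(_ActiveEffect(term, beta, sigma_b2, s2, col))
            self._active_keys.add(term)
            if self._collapsed:
                self._ll = self._ll + dll
            else:
                self.resid = resid_new

    def _move_delete(self) -> None:
        if not self.active:
            return
        j = int(self.rng.integers(len(self.active)))
        e = self.active[j]
        w = self.priors.w(e.term.kind)
        p_add, p_del = self.config.move_probs[0], self.config.move_probs[1]
        kind_i = self._kinds.index(e.term.kind)
        log_q_add = (
            math.log(p_add)
            + math.log(self._kind_probs[kind_i])
            - math.log(self.model.catalog.count(e.term.kind))
        )
        log_q_del = math.log(p_del) - math.log(len(self.active))
        if self._collapsed:
            popped = self.active.pop(j)
            ll_new = self._marginal_ll()
            dll = ll_new - self._ll
            self.active.insert(j, popped)
        else:
            resid_new = self.resid + e.beta * e.col
            dll = self._loglik_delta_from_resid(resid_new)
        log_r = dll + math.log((1.0 - w) / w) + log_q_add - log_q_del
        if math.log(self.rng.uniform()) < log_r:
            self.active.pop(j)
            self._active_keys.discard(e.term)
            if self._collapsed:
                self._ll = self._ll + dll
            else:
                self.resid = resid_new

    def _move_position(self) -> None:
        """Move one SNP slot of a random active effect to a uniform SNP."""
        if not self.active:
            return
        j = int(self.rng.integers(len(self.active)))
        e = self.active[j]
        t = e.term
        new_snp = int(self.rng.integers(self.model.p))
        if t.kind == MAIN:
            new_term = EffectTerm(MAIN, new_snp)
        elif t.kind == EPISTATIC:
            slot = int(self.rng.integers(2))
            other = t.snp2 if slot == 0 else t.snp1
            if new_snp == other:
                return
            new_term = EffectTerm(EPISTATIC, min(new_snp, other), max(new_snp, other))
        else:
            new_term = EffectTerm(SNP_COV, new_snp, cov=t.cov)
        if new_term == t or new_term in self._active_keys:
            return
        col = self.model.design_column(new_term)
        s2 = self._s_beta2(new_term, col)
        # the sigma_beta^2 prior scale is column-dependent; account for it
        log_prior_sb = 0.0
        if self.config.fixed_sigma_beta2 is None:
            nu = self.priors.nu_beta
            log_prior_sb = _log_invchi2(e.sigma_b2, nu, s2) - _log_invchi2(
                e.sigma_b2, nu, e.s2
            )
        if self._collapsed:
            old = (e.term, e.col, e.s2)
            e.term, e.col, e.col_ss, e.s2 = new_term, col, float(col @ col), s2
            ll_new = self._marginal_ll()
            dll = ll_new - self._ll
            e.term, e.col, e.s2 = old
            e.col_ss = float(e.col @ e.col)
        else:
            resid_new = self.resid + e.beta * (e.col - col)
            dll = self._loglik_delta_from_resid(resid_new)
        if math.log(self.rng.uniform()) < dll + log_prior_sb:
            self._active_keys.discard(t)
            self._active_keys.add(new_term)
            if not self._collapsed:
                self.resid = self.resid + e.beta * (e.col - col)
            e.term, e.col, e.col_ss, e.s2 = new_term, col, float(col @ col), s2
            if self._collapsed:
                self._ll = self._ll + dll

    def _move_refresh(self) -> None:
        if not self.active:
            return
        j = int(self.rng.integers(len(self.active)))
        if self._collapsed:
            self._rw_beta(j)
        else:
            self._gibbs_beta(j)

    # ------------------------------------------------------------------ #
    # collapsed (sigma^2 = 0) random-walk updates

    def _rw_accept(self, log_prior_delta: float, apply, revert) -> bool:
        apply()
        ll_new = self._marginal_ll()
        log_r = ll_new - self._ll + log_prior_delta
        if math.log(self.rng.uniform()) < log_r:
            self._ll = ll_new
            return True
        revert()
        return False

    def _rw_beta(self, j: int) -> None:
        e = self.active[j]
        old = e.beta
        step = self.config.rw_scale * math.sqrt(e.sigma_b2)
        new = old + step * self.rng.standard_normal()
        lp = (old * old - new * new) / (2.0 * e.sigma_b2)

        def apply():
            e.beta = new

        def revert():
            e.beta = old

        self._rw_accept(lp, apply, revert)

    def _collapsed_sweep(self) -> None:
        cfg = self.config
        for _ in range(cfg.mh_moves_per_sweep):
            if "gamma" in cfg.update:
                self.mh_move()
        pr = self.priors
        if "mu" in cfg.update:
            old = self.mu
            new = old + cfg.rw_scale * math.sqrt(pr.tau02) * self.rng.standard_normal()
            lp = ((old - pr.eta0) ** 2 - (new - pr.eta0) ** 2) / (2.0 * pr.tau02)
            self._rw_accept(
                lp,
                lambda: setattr(self, "mu", new),
                lambda: setattr(self, "mu", old),
            )
        if "beta_cov" in cfg.update:
            for jj in range(self.model.q):
                old = self.beta_cov[jj]
                new = old + cfg.rw_scale * math.sqrt(
                    pr.cov_effect_var
                ) * self.rng.standard_normal() * 0.1
                lp = (old * old - new * new) / (2.0 * pr.cov_effect_var)

                def apply(jj=jj, new=new):
                    self.beta_cov[jj] = new

                def revert(jj=jj, old=old):
                    self.beta_cov[jj] = old

                self._rw_accept(lp, apply, revert)
        if "beta" in cfg.update:
            for j in range(len(self.active)):
                self._rw_beta(j)
        if "sigma_beta2" in cfg.update:
            self.update_sigma_beta2()
        if self.model.random_effects:
            if "delta" in cfg.update:
                for l in range(self.k):
                    old = self.delta[l]
                    # reflected random walk keeps the proposal symmetric on [0, inf)
                    new = abs(old + cfg.rw_scale * self.rng.standard_normal())
                    lp = (
                        (old - pr.delta_m0) ** 2 - (new - pr.delta_m0) ** 2
                    ) / (2.0 * pr.delta_s02)

                    def apply(l=l, new=new):
                        self.delta[l] = new

                    def revert(l=l, old=old):
                        self.delta[l] = old

                    self._rw_accept(lp, apply, revert)
            if "psi" in cfg.update:
                for j in range(self.n_psi):
                    old = self.psi[j]
                    new = old + cfg.rw_scale * self.rng.standard_normal()
                    lp = (
                        (old - pr.psi_mean) ** 2 - (new - pr.psi_mean) ** 2
                    ) / (2.0 * pr.psi_var)

                    def apply(j=j, new=new):
                        self.psi[j] = new
                        self.Psi = psi_matrix(self.psi, self.k)

                    def revert(j=j, old=old):
                        self.psi[j] = old
                        self.Psi = psi_matrix(self.psi, self.k)

                    self._rw_accept(lp, apply, revert)

    # ------------------------------------------------------------------ #
    # sweeps and the chain driver

    def sweep(self) -> None:
        if self._collapsed:
            self._collapsed_sweep()
            return
        cfg = self.config
        for _ in range(cfg.mh_moves_per_sweep):
            if "gamma" in cfg.update:
                self.mh_move()
        if "beta" in cfg.update:
            self.update_active_betas()
        if "sigma_beta2" in cfg.update:
            self.update_sigma_beta2()
        if "beta_cov" in cfg.update:
            self.update_beta_cov()
        if self.model.random_effects:
            if "b" in cfg.update:
                self.update_b()
            if "delta" in cfg.update:
                self.update_delta()
            if "psi" in cfg.update:
                self.update_psi()
        if "mu" in cfg.update:
            self.update_mu()
        if "sigma2" in cfg.update:
            self.update_sigma2()

    def run(self, progress: bool = False) -> ChainResult:
        cfg = self.config
        T = cfg.n_samples
        k, npsi, q = self.k, self.n_psi, self.model.q
        out_mu = np.empty(T)
        out_s2 = np.empty(T)
        out_delta = np.empty((T, k))
        out_psi = np.empty((T, npsi))
        out_bcov = np.empty((T, q))
        out_ll = np.empty(T)
        out_nact = np.empty(T, dtype=int)
        actives: list = []
        fitted_sum = np.zeros(self.N)
        out_b = np.empty((T, self.model.n, k)) if cfg.store_b else None

        for _ in range(cfg.burn_in):
            self.sweep()
        t = 0
        for it in range(1, cfg.n_iter + 1):
            self.sweep()
            if it % cfg.thin == 0:
                out_mu[t] = self.mu
                out_s2[t] = self.sigma2
                out_delta[t] = self.delta
                out_psi[t] = self.psi
                out_bcov[t] = self.beta_cov
                out_nact[t] = len(self.active)
                actives.append([(e.term, e.beta) for e in self.active])
                if self._collapsed:
                    fitted = self._fixed_mean()
                    out_ll[t] = self._ll
                else:
                    fitted = self.y - self.resid - self.re
                    out_ll[t] = self.model.marginal_loglik_from_mean(
                        fitted, self.delta, self.psi, self.sigma2
                    )
                fitted_sum += fitted
                if cfg.store_b:
                    out_b[t] = self.b
                t += 1
        return ChainResult(
            mu=out_mu,
            sigma2=out_s2,
            delta=out_delta,
            psi=out_psi,
            beta_cov=out_bcov,
            loglik=out_ll,
            actives=actives,
            mean_fitted=fitted_sum / max(T, 1),
            n_active=out_nact,
            p=self.model.p,
            q=q,
            config=cfg,
            priors=self.priors,
            b=out_b,
        )


def run_mcmc(
    model: LongitudinalGridModel, priors: PriorSpec, config: McmcConfig
) -> ChainResult:
    """Run one seeded chain; a fixed seed fully determines the output."""
    return GibbsSampler(model, priors, config).run()
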