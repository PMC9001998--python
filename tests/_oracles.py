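"""Shared independent oracles for the test suite: numerical grid integration
of full conditionals, exhaustive model-space enumeration, and small dataset
builders.  These deliberately avoid the conjugate algebra and residual
bookkeeping inside the sampler, relying only on the model's likelihood
evaluators and explicit prior densities."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from gridlong import (
    GibbsSampler,
    LongitudinalGridModel,
    McmcConfig,
    ModelParams,
    PriorSpec,
)
from gridlong.effects import EffectTerm


def ks_distance(samples: np.ndarray, xs: np.ndarray, cdf: np.ndarray) -> float:
    """Sup distance between the empirical CDF of samples and a numeric CDF
    given on the grid xs."""
    samples = np.sort(np.asarray(samples, float))
    F = np.interp(samples, xs, cdf)
    n = samples.size
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    return float(max(np.abs(emp_hi - F).max(), np.abs(emp_lo - F).max()))


def grid_cdf(xs: np.ndarray, logdens: np.ndarray) -> np.ndarray:
    """Normalized CDF from unnormalized log density values on a grid."""
    logdens = logdens - logdens.max()
    dens = np.exp(logdens)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(xs))])
    return cdf / cdf[-1]


def conditional_logdens(model, params: ModelParams, setter, logprior, xs) -> np.ndarray:
    """Unnormalized log conditional density of one coordinate over grid xs:
    conditional likelihood (given b) times the coordinate's prior."""
    out = np.empty(xs.size)
    for i, x in enumerate(xs):
        p = setter(params, x)
        out[i] = model.conditional_loglik(p) + logprior(x)
    return out


def tiny_model(seed: int = 5, k: int = 2, p: int = 3, n: int = 5) -> LongitudinalGridModel:
    """A small irregular dataset (5 subjects, 2-3 observations each, off-grid
    times) on a k-point grid over [0, 1]."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        ni = 2 + (i % 2)
        times = np.sort(rng.uniform(0, 1, ni))
        times[0] = 0.0 if i == 0 else times[0]  # pin the range
        times[-1] = 1.0 if i == 0 else times[-1]
        for t in times:
            rows.append((f"s{i}", t, float(rng.normal())))
    pheno = pd.DataFrame(rows, columns=["subject_id", "time", "value"])
    G = rng.binomial(2, 0.4, size=(n, p)).astype(float)
    geno = pd.DataFrame(G, index=[f"s{i}" for i in range(n)], columns=[f"g{j}" for j in range(p)])
    # simulate a trait with one main effect and grid random effects
    model0 = LongitudinalGridModel(pheno, geno, grid=np.linspace(0, 1, k))
    delta = np.linspace(1.0, 0.7, k)
    psi = 0.5 * np.ones(k * (k - 1) // 2)
    from gridlong.grid import CholeskyFactors

    b = rng.standard_normal((n, k))
    L = CholeskyFactors(delta, psi).L()
    re = np.einsum("ok,ok->o", model0.W, (b @ L.T)[model0.subj_idx])
    y = 1.5 + 0.8 * G[model0.subj_idx, 0] + re + rng.normal(0, 1.0, model0.N)
    pheno = pheno.assign(value=y)
    return LongitudinalGridModel(pheno, geno, grid=np.linspace(0, 1, k))


def reference_params(model, seed: int = 3) -> ModelParams:
    """A fixed, nontrivial parameter state used when testing one conditional."""
    rng = np.random.default_rng(seed)
    k = model.k
    return ModelParams(
        mu=1.2,
        sigma2=0.8,
        delta=np.linspace(0.9, 0.6, k),
        psi=0.4 * np.ones(k * (k - 1) // 2),
        beta_cov=np.array([0.3] * model.q),
        active=[(EffectTerm("main", 0), 0.7)],
        b=rng.standard_normal((model.n, k)),
    )


def make_sampler(model, priors=None, **cfg_kw) -> GibbsSampler:
    cfg = McmcConfig(seed=cfg_kw.pop("seed", 0), **cfg_kw)
    return GibbsSampler(model, priors or model.priors, cfg)


# --------------------------------------------------------------------- #
# exhaustive enumeration of the gamma model space (no random effects)


def enumerate_gamma_posterior(model, priors: PriorSpec, sigma_beta2: float, sigma2: float, mu: float):
    """Exact P(gamma | y) for every subset of the effect catalog, with beta
    integrated out analytically: y ~ N(mu, sigma_beta2 X X' + sigma2 I)."""
    from itertools import combinations

    terms = list(model.catalog.terms())
    y = model.y
    N = model.N
    logw = {
        "main": np.log(priors.w_main / (1 - priors.w_main)),
        "epistatic": np.log(priors.w_epistatic / (1 - priors.w_epistatic)),
        "snp_covariate": np.log(priors.w_snp_cov / (1 - priors.w_snp_cov)),
    }
    states, logp = [], []
    for r in range(len(terms) + 1):
        for subset in combinations(range(len(terms)), r):
            X = np.column_stack([model.design_column(terms[j]) for j in subset]) if subset else np.zeros((N, 0))
            S = sigma_beta2 * (X @ X.T) + sigma2 * np.eye(N)
            resid = y - mu
            sign, logdet = np.linalg.slogdet(S)
            ll = -0.5 * (N * np.log(2 * np.pi) + logdet + resid @ np.linalg.solve(S, resid))
            lp = ll + sum(logw[terms[j].kind] for j in subset)
            states.append(frozenset(terms[j] for j in subset))
            logp.append(lp)
    logp = np.asarray(logp)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    return states, prob


def chain_gamma_frequencies(chain, states):
    """Empirical visit frequencies of the enumerated gamma states."""
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros(len(states))
    for snap in chain.actives:
        key = frozenset(term for term, _ in snap)
        counts[index[key]] += 1
    return counts / max(len(chain.actives), 1)
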