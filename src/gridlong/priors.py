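"""Prior specifications for the grid-based Bayesian mixed model.

Defaults follow the conjugate scheme the sampler exploits:

* inclusion indicators gamma_a ~ Bernoulli(w_a) with w_a per effect type;
  effect positions lambda uniform over SNPs;
* beta_a | gamma_a=1 ~ N(0, sigma_beta_a^2) with
  sigma_beta_a^2 ~ scaled-inv-chi2(nu_beta, s_beta_a^2),
  s_beta_a^2 = (nu_beta - 2) E(h_a) V / (nu_beta V_a) so that the prior mean
  of beta_a^2 corresponds to an expected per-effect heritability E(h_a)
  (V = total phenotypic variance, V_a = sample variance of the effect's
  design column);
* overall mean mu ~ N(eta_0, tau_0^2) with empirical eta_0 = ybar,
  tau_0^2 = s_y^2;
* residual variance sigma^2 ~ scaled-inv-chi2(nu_sigma, s_sigma^2);
* delta_l ~ half-normal N+(m_l0, s_l0^2), default N+(0, 30);
* psi ~ N(psi_0, R_0), default N(0, 0.5 I).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PriorSpec", "init_priors", "s_beta2"]


@dataclass(frozen=True)
class PriorSpec:
    # per-type inclusion probabilities
    w_main: float
    w_epistatic: float
    w_snp_cov: float
    # genetic-effect variance hyperpriors
    nu_beta: float = 6.0
    expected_h: float = 0.1
    phenotype_var: float = 1.0  # V, total phenotypic variance
    # overall mean
    eta0: float = 0.0
    tau02: float = 1.0
    # residual variance
    nu_sigma: float = 2.0
    s_sigma2: float = 1.0
    # delta half-normal N+(m0, s0^2), shared across grid points
    delta_m0: float = 0.0
    delta_s02: float = 30.0
    # psi normal prior N(psi0, R0), R0 = psi_var * I
    psi_mean: float = 0.0
    psi_var: float = 0.5
    # always-included covariate coefficients: N(0, cov_effect_var)
    cov_effect_var: float = 100.0

    def w(self, kind: str) -> float:
        return {
            "main": self.w_main,
            "epistatic": self.w_epistatic,
            "snp_covariate": self.w_snp_cov,
        }[kind]

    def expected_active(self, catalog) -> float:
        return (
            self.w_main * catalog.n_main
            + self.w_epistatic * catalog.n_epistatic
            + self.w_snp_cov * catalog.n_snp_cov
        )

    def replace(self, **kw) -> "PriorSpec":
        return replace(self, **kw)


def s_beta2(priors: PriorSpec, col_var: float) -> float:
    """Prior scale for one effect's variance:
    ``s_beta_a^2 = (nu_beta - 2) E(h_a) V / (nu_beta V_a)``.

    A monomorphic (zero-variance) design column has no defined heritability;
    the scale falls back to ``V_a = 1`` so the prior stays proper.
    """
    va = col_var if col_var > 0 else 1.0
    return (
        (priors.nu_beta - 2.0)
        * priors.expected_h
        * priors.phenotype_var
        / (priors.nu_beta * va)
    )


def init_priors(
    y: np.ndarray,
    catalog,
    expected_main: float = 3.0,
    expected_epistatic: float = 1.0,
    expected_snp_cov: float = 1.0,
    **overrides,
) -> PriorSpec:
    """Empirical default priors for a phenotype vector and effect catalog.

    ``eta_0`` and ``tau_0^2`` are the grand mean and sample variance of the
    trait; the inclusion probabilities are set so the prior expected numbers
    of active main / epistatic / SNP-covariate effects are
    ``(expected_main, expected_epistatic, expected_snp_cov)``.
    """
    y = np.asarray(y, dtype=float)
    var_y = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    if var_y <= 0:
        raise ValueError("phenotype has zero variance; cannot set priors")
    spec = PriorSpec(
        w_main=min(expected_main / catalog.n_main, 0.5),
        w_epistatic=min(expected_epistatic / catalog.n_epistatic, 0.5)
        if catalog.n_epistatic
        else 1e-12,
        w_snp_cov=min(expected_snp_cov / catalog.n_snp_cov, 0.5),
        phenotype_var=var_y,
        eta0=float(np.mean(y)),
        tau02=var_y,
        nu_sigma=2.0,
        s_sigma2=var_y,
        cov_effect_var=100.0 * var_y,
    )
    return spec.replace(**overrides) if overrides else spec
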