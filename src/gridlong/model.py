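"""The grid-based Bayesian mixed model for longitudinal genetic association.

For subject ``i`` with ``n_i`` observations the model is

    y_i = mu 1 + x_i Gamma beta + p_i Delta Psi b_i + e_i,
    b_i ~ N(0, I_k),   e_i ~ N(0, sigma^2 I_{n_i}),

where ``x_i`` collects the always-included covariate block (standardized time
first) and the candidate genetic effect columns (main, epistatic,
SNP-covariate), ``Gamma`` carries the binary inclusion indicators, ``p_i`` is
the linear-interpolation matrix onto ``k`` grid time points, and
``D = Delta Psi Psi' Delta`` is the grid-level random-effect covariance.
Marginally ``y_i ~ N(mu 1 + x_i Gamma beta, p_i D p_i' + sigma^2 I)``.

:class:`LongitudinalGridModel` holds the data and design bookkeeping;
``fit()`` runs the Metropolis-Hastings-within-Gibbs sampler and returns a
:class:`~gridlong.results.MixedModelResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import identifiability as ident
from .effects import EffectCatalog, EffectTerm, build_design_column
from .grid import (
    CholeskyFactors,
    GridSpec,
    build_interp_row,
    default_grid,
    psi_matrix,
    reconstruct_D,
)
from .priors import PriorSpec, init_priors

__all__ = ["LongitudinalGridModel", "ModelParams"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelParams:
    """One full parameter configuration of the mixed model."""

    mu: float
    sigma2: float
    delta: np.ndarray
    psi: np.ndarray
    beta_cov: np.ndarray  # always-included covariate coefficients (length q)
    active: list = field(default_factory=list)  # [(EffectTerm, beta), ...]
    b: Optional[np.ndarray] = None  # n x k random coordinates


class LongitudinalGridModel:
    """Grid-based Bayesian mixed model bound to one dataset.

    Parameters
    ----------
    phenotypes : DataFrame
        Long format, one row per observation, with columns ``subject_id``,
        ``time``, ``value`` plus optional extra covariate columns.
    genotypes : DataFrame
        ``n x p`` additive genotypes (0/1/2 or dosages in [0, 2]), indexed by
        subject id, one column per SNP.
    grid : int, sequence of float, or GridSpec
        Number of grid points (auto-placed equally spaced over the observed
        time range) or an explicit grid.
    covariates : sequence of str, optional
        Extra phenotype columns to include in the always-on covariate block,
        after standardized time.
    priors : PriorSpec, optional
        Defaults to :func:`gridlong.priors.init_priors` on the data.
    random_effects : bool
        If False the grid random effects are dropped (delta frozen at zero);
        this is the cross-sectional variant used for single-time-point
        comparison analyses.
    """

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        genotypes: pd.DataFrame,
        grid: int | Sequence[float] | GridSpec = 3,
        covariates: Optional[Sequence[str]] = None,
        priors: Optional[PriorSpec] = None,
        random_effects: bool = True,
        subject_col: str = "subject_id",
        time_col: str = "time",
        value_col: str = "value",
    ):
        required = {subject_col, time_col, value_col}
        missing = required - set(phenotypes.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        pheno = phenotypes.sort_values([subject_col, time_col], kind="stable")
        pheno = pheno.reset_index(drop=True)
        if pheno.duplicated([subject_col, time_col]).any():
            raise ValueError("duplicate (subject, time) rows in phenotype table")
        values = pd.to_numeric(pheno[value_col], errors="raise").to_numpy(float)

        subjects = pheno[subject_col].unique()
        missing_geno = [s for s in subjects if s not in genotypes.index]
        if missing_geno:
            raise ValueError(f"subjects without genotypes: {missing_geno[:5]}")
        G = genotypes.loc[subjects].to_numpy(float)
        if np.isnan(G).any():
            # mean imputation per SNP (matches complete-data simulations;
            # real input may carry missing dosages)
            col_mean = np.nanmean(G, axis=0)
            inds = np.where(np.isnan(G))
            G[inds] = col_mean[inds[1]]
        if G.min() < 0 or G.max() > 2:
            raise ValueError("genotypes must be additive codes/dosages in [0, 2]")

        self.subjects = subjects
        self.snp_ids = list(genotypes.columns)
        self.G = G
        self.n = len(subjects)
        self.p = G.shape[1]
        self.y = values
        self.N = values.size

        subj_map = {s: i for i, s in enumerate(subjects)}
        self.subj_idx = pheno[subject_col].map(subj_map).to_numpy(int)
        self.times_raw = pheno[time_col].to_numpy(float)
        self.n_i = np.bincount(self.subj_idx, minlength=self.n)

        # covariate block: standardized time first, then user covariates
        t = self.times_raw
        sd = t.std()
        std_time = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
        cov_cols = [std_time]
        self.covariate_names = ["time_std"]
        for c in covariates or []:
            cov_cols.append(pd.to_numeric(pheno[c], errors="raise").to_numpy(float))
            self.covariate_names.append(c)
        self.C = np.column_stack(cov_cols)
        self.q = self.C.shape[1]

        if isinstance(grid, GridSpec):
            self.grid = grid
        elif np.isscalar(grid):
            self.grid = default_grid(self.times_raw, int(grid))
        else:
            self.grid = GridSpec(np.asarray(grid, dtype=float))
        if not self.grid.covers(self.times_raw):
            raise ValueError("grid does not cover the observed time range")
        self.k = self.grid.k
        self.W = np.vstack([build_interp_row(t, self.grid) for t in self.times_raw])

        # padded per-subject layout for batched subject-level linear algebra
        m = int(self.n_i.max())
        self.pad_width = m
        pad_idx = np.full((self.n, m), self.N, dtype=int)  # N -> zero slot
        pos = np.zeros(self.n, dtype=int)
        for o, i in enumerate(self.subj_idx):
            pad_idx[i, pos[i]] = o
            pos[i] += 1
        self.pad_idx = pad_idx
        self.pad_mask = pad_idx < self.N
        Wext = np.vstack([self.W, np.zeros((1, self.k))])
        self.W_pad = Wext[pad_idx]  # n x m x k, zero rows in padding

        self.catalog = EffectCatalog(self.p, self.q)
        self.priors = priors if priors is not None else init_priors(self.y, self.catalog)
        self.random_effects = random_effects
        self.pheno_frame = pheno

    # ------------------------------------------------------------------ #
    # construction helpers

    @classmethod
    def from_files(
        cls, phenotype_path, genotype_path, grid=3, **kw
    ) -> "LongitudinalGridModel":
        from .io import read_genotypes, read_phenotypes

        return cls(read_phenotypes(phenotype_path), read_genotypes(genotype_path), grid=grid, **kw)

    def with_grid(self, grid) -> "LongitudinalGridModel":
        """Same data, different grid (used by the k-selection scan)."""
        return LongitudinalGridModel(
            self.pheno_frame,
            pd.DataFrame(self.G, index=self.subjects, columns=self.snp_ids),
            grid=grid,
            covariates=self.covariate_names[1:],
            priors=self.priors,
            random_effects=self.random_effects,
        )

    # ------------------------------------------------------------------ #
    # identifiability

    def interp_matrices(self) -> list[np.ndarray]:
        return [self.W_pad[i][self.pad_mask[i]] for i in range(self.n)]

    def check_identifiability(self) -> ident.IdentifiabilityReport:
        return ident.is_identifiable(ident.build_A(self.interp_matrices()))

    # ------------------------------------------------------------------ #
    # design and mean structure

    def design_column(self, term: EffectTerm) -> np.ndarray:
        return build_design_column(term, self.G, self.subj_idx, self.C)

    def mean_vector(self, params: ModelParams) -> np.ndarray:
        """mu + x Gamma beta (fixed part, no random effects)."""
        mean = params.mu + self.C @ np.asarray(params.beta_cov, dtype=float)
        for term, beta in params.active:
            mean = mean + beta * self.design_column(term)
        return mean

    def random_effect_values(self, params: ModelParams) -> np.ndarray:
        """Per-observation contribution p_i Delta Psi b_i."""
        if params.b is None:
            raise ValueError("params.b required")
        L = CholeskyFactors(params.delta, params.psi).L()
        nu = params.b @ L.T  # n x k grid-level effects nu_i = L b_i
        return np.einsum("ok,ok->o", self.W, nu[self.subj_idx])

    # ------------------------------------------------------------------ #
    # likelihoods

    def marginal_loglik(self, params: ModelParams) -> float:
        """log P(y | gamma, theta) with the random coordinates integrated out:
        sum over subjects of the N(mean_i, p_i D p_i' + sigma^2 I) log density.
        """
        return self.marginal_loglik_from_mean(
            self.mean_vector(params), params.delta, params.psi, params.sigma2
        )

    def marginal_loglik_from_mean(
        self, mean: np.ndarray, delta, psi, sigma2: float
    ) -> float:
        resid = self.y - np.asarray(mean, dtype=float)
        delta = np.asarray(delta, dtype=float)
        if sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if sigma2 == 0.0:
            return self._marginal_loglik_sigma0(resid, delta, psi)
        L = CholeskyFactors(delta, psi).L()
        V = self.W_pad @ L  # n x m x k
        S = V @ V.transpose(0, 2, 1)
        m = self.pad_width
        S[:, np.arange(m), np.arange(m)] += sigma2
        r = np.append(resid, 0.0)[self.pad_idx]  # n x m, zero padding
        Lc = np.linalg.cholesky(S)
        z = np.linalg.solve(Lc, r[:, :, None])[:, :, 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2)))
        quad = float(np.sum(z * z))
        n_pad = self.n * m - self.N
        ll = -0.5 * (self.n * m * _LOG2PI + logdet + quad)
        # padded slots are unit-variance-free N(0, sigma2) zeros; remove them
        ll -= n_pad * (-0.5 * (_LOG2PI + np.log(sigma2)))
        return float(ll)

    def _marginal_loglik_sigma0(self, resid, delta, psi) -> float:
        """Singular-covariance likelihood via the pseudo-determinant; residual
        mass outside the column space of p_i Delta Psi contributes -inf."""
        L = CholeskyFactors(delta, psi).L()
        tol = 1e-8
        total = 0.0
        for i in range(self.n):
            Vi = self.W_pad[i][self.pad_mask[i]] @ L
            ri = resid[self.pad_idx[i][self.pad_mask[i]]]
            U, s, _ = np.linalg.svd(Vi, full_matrices=False)
            keep = s > tol * max(1.0, s.max() if s.size else 0.0)
            rank = int(keep.sum())
            proj = U[:, keep].T @ ri
            ortho = ri - U[:, keep] @ proj
            if np.linalg.norm(ortho) > 1e-6 * max(1.0, np.linalg.norm(ri)):
                return float("-inf")
            total += -0.5 * (
                rank * _LOG2PI
                + 2.0 * float(np.sum(np.log(s[keep])))
                + float(np.sum((proj / s[keep]) ** 2))
            )
        return float(total)

    def conditional_loglik(self, params: ModelParams) -> float:
        """log P(y | gamma, theta, b): independent normal residuals given the
        realized random effects."""
        resid = self.y - self.mean_vector(params) - self.random_effect_values(params)
        if params.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if params.sigma2 == 0.0:
            return 0.0 if float(np.max(np.abs(resid))) < 1e-8 else float("-inf")
        return float(
            -0.5
            * (
                self.N * (_LOG2PI + np.log(params.sigma2))
                + float(resid @ resid) / params.sigma2
            )
        )

    def D(self, params: ModelParams) -> np.ndarray:
        return reconstruct_D(CholeskyFactors(params.delta, params.psi))

    # ------------------------------------------------------------------ #
    # fitting

    def fit(
        self,
        n_iter: int = 400_000,
        burn_in: int = 1000,
        thin: int = 40,
        seed: int | None = 0,
        config=None,
        check_identifiability: bool = True,
        fix_sigma2: bool = False,
        **config_overrides,
    ):
        """Run the MH-within-Gibbs sampler and return results.

        ``fix_sigma2=True`` freezes sigma^2 at zero (the documented escape for
        non-identifiable designs) and switches to the collapsed sampler.
        """
        from .results import MixedModelResults
        from .sampler import McmcConfig, run_mcmc

        if config is None:
            config = McmcConfig(
                n_iter=n_iter,
                burn_in=burn_in,
                thin=thin,
                seed=0 if seed is None else int(seed),
                fix_sigma2=fix_sigma2,
                **config_overrides,
            )
        if self.random_effects and check_identifiability:
            report = self.check_identifiability()
            adjust = ident.resolve_nonidentifiable(
                report, fix_sigma2=config.fix_sigma2
            )
            if adjust["fix_sigma2"] and not config.fix_sigma2:
                config = config.replace(fix_sigma2=True)
        else:
            report = None
        chain = run_mcmc(self, self.priors, config)
        return MixedModelResults(self, chain, identifiability=report)
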