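"""Synthetic longitudinal genetic data generator.

Emulates the simulation designs used to validate the grid-based mixed model:
independent Hardy-Weinberg genotypes with MAF >= 5% stand in for real
haplotype panels (no linkage disequilibrium), each subject carries 3-7
measurements at times uniform on [0, 1] (total observation count fixed
exactly), the grid-level random effects are nu_i ~ N(0, D) with
D = Delta Psi Psi' Delta built from the true (delta, psi), the residual
variance is sigma^2 = 1, and the genetic signal follows one of six effect
models (main-only through ten SNP-time interactions) scaled so the trait
heritability hits a target (40% by default).

Heritability here is Var(c_g * S) / (Var(c_g * S) + V_re + sigma^2), where S
is the unscaled signal including its time term when the model has one (the
whole bracket is scaled by c_g in the generative equations) and V_re is the
average per-observation random-effect variance diag(p_i D p_i').
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .effects import EPISTATIC, MAIN, SNP_COV, EffectTerm
from .grid import CholeskyFactors, GridSpec, build_interp_row, reconstruct_D

__all__ = [
    "SimulationDesign",
    "SimulatedData",
    "gen_genotypes",
    "gen_times",
    "calibrate_cg",
    "gen_phenotypes",
    "simulate",
    "default_delta",
    "default_psi",
]

_DELTA_DEFAULTS = {
    2: (1.0, 1.2),
    3: (1.0, 1.2, 0.8),
    4: (1.0, 1.2, 0.8, 0.7),
}
_PSI_DEFAULTS = {
    2: (0.6,),
    3: (0.6, 0.4, 0.6),
    4: (0.6, 0.4, 0.6, 0.2, 0.4, 0.6),
}

# effect templates on the 10 causal SNPs: (n_main, epistatic pairs, n snp-time,
# standalone time term inside the scaled bracket)
_SETUPS = {
    1: dict(n_main=10, n_pairs=0, n_gxt=0, time_term=True),
    2: dict(n_main=6, n_pairs=2, n_gxt=0, time_term=True),
    3: dict(n_main=0, n_pairs=5, n_gxt=0, time_term=True),
    4: dict(n_main=8, n_pairs=0, n_gxt=2, time_term=False),
    5: dict(n_main=5, n_pairs=0, n_gxt=5, time_term=False),
    6: dict(n_main=0, n_pairs=0, n_gxt=10, time_term=False),
}


def default_delta(k: int) -> np.ndarray:
    return np.asarray(_DELTA_DEFAULTS[k], dtype=float)


def default_psi(k: int) -> np.ndarray:
    return np.asarray(_PSI_DEFAULTS[k], dtype=float)


@dataclass(frozen=True)
class SimulationDesign:
    """One simulation configuration (defaults: the main-effects design with
    400 subjects, 2,000 observations, 1,000 SNPs, 1% causal, h^2 = 40%,
    k = 3 true grid points)."""

    setup: int = 1
    k_true: int = 3
    n: int = 400
    N: int = 2000
    p: int = 1000
    n_causal: int = 10
    h2: float = 0.40
    sigma2: float = 1.0
    maf_range: tuple = (0.05, 0.5)
    delta: Optional[tuple] = None
    psi: Optional[tuple] = None

    def __post_init__(self):
        if self.setup not in _SETUPS:
            raise ValueError(f"setup must be one of {sorted(_SETUPS)}")
        if self.n_causal > self.p:
            raise ValueError("more causal SNPs than SNPs")
        if self.setup != 1 and self.n_causal != 10:
            raise ValueError("setups 2-6 are defined for exactly 10 causal SNPs")

    def true_factors(self) -> CholeskyFactors:
        d = np.asarray(self.delta, float) if self.delta is not None else default_delta(self.k_true)
        s = np.asarray(self.psi, float) if self.psi is not None else default_psi(self.k_true)
        return CholeskyFactors(d, s)

    def grid(self) -> GridSpec:
        return GridSpec(np.linspace(0.0, 1.0, self.k_true))

    def replace(self, **kw) -> "SimulationDesign":
        return replace(self, **kw)


@dataclass
class SimulatedData:
    genotypes: pd.DataFrame  # n x p, indexed by subject id
    phenotypes: pd.DataFrame  # long format: subject_id, time, value
    truth: dict  # ground-truth record for recovery / power evaluation

    @property
    def causal_mask(self) -> np.ndarray:
        mask = np.zeros(self.genotypes.shape[1], dtype=bool)
        mask[self.truth["causal_snps"]] = True
        return mask


def gen_genotypes(
    n: int,
    p: int,
    maf_range: tuple = (0.05, 0.5),
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotype matrix: column j ~ Binomial(2, maf_j), maf_j ~ U(maf_range).

    Columns whose realized minor-allele frequency collapses below half the
    lower bound are redrawn, so no simulated SNP is effectively monomorphic.
    Returns (genotypes, mafs).
    """
    rng = np.random.default_rng(rng)
    lo, hi = maf_range
    maf = rng.uniform(lo, hi, size=p)
    G = rng.binomial(2, maf, size=(n, p)).astype(float)
    floor = 0.5 * lo
    for _ in range(100):
        realized = G.mean(axis=0) / 2.0
        realized = np.minimum(realized, 1.0 - realized)
        bad = realized < floor
        if not bad.any():
            break
        G[:, bad] = rng.binomial(2, maf[bad], size=(n, int(bad.sum())))
    return G, maf


def gen_times(
    n: int,
    N: int,
    n_i_range: tuple = (3, 7),
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-subject observation times, U[0, 1], with counts n_i drawn uniformly
    from the given range and then nudged by +/-1 steps so that sum n_i = N
    exactly.  Returns (times per subject, standardized time covariate over all
    N observations in subject order)."""
    rng = np.random.default_rng(rng)
    lo, hi = n_i_range
    if not lo * n <= N <= hi * n:
        raise ValueError(f"N={N} infeasible for n={n} subjects with n_i in [{lo},{hi}]")
    n_i = rng.integers(lo, hi + 1, size=n)
    diff = int(n_i.sum()) - N
    while diff != 0:
        i = int(rng.integers(n))
        if diff > 0 and n_i[i] > lo:
            n_i[i] -= 1
            diff -= 1
        elif diff < 0 and n_i[i] < hi:
            n_i[i] += 1
            diff += 1
    times = [np.sort(rng.uniform(0.0, 1.0, size=int(m))) for m in n_i]
    flat = np.concatenate(times)
    std = (flat - flat.mean()) / flat.std()
    return times, std


def _signal_terms(design: SimulationDesign, causal: np.ndarray) -> list[EffectTerm]:
    """The causal effect terms implied by the setup template, laid out over the
    causal SNPs in their drawn order (mains first, then pairs, then SNP-time)."""
    spec = dict(_SETUPS[design.setup])
    if design.setup == 1:  # main-only design scales to any causal count
        spec["n_main"] = design.n_causal
    terms: list[EffectTerm] = []
    pos = 0
    for _ in range(spec["n_main"]):
        terms.append(EffectTerm(MAIN, int(causal[pos])))
        pos += 1
    for _ in range(spec["n_pairs"]):
        a, b = int(causal[pos]), int(causal[pos + 1])
        terms.append(EffectTerm(EPISTATIC, min(a, b), max(a, b)))
        pos += 2
    for _ in range(spec["n_gxt"]):
        terms.append(EffectTerm(SNP_COV, int(causal[pos]), cov=0))
        pos += 1
    return terms


def _unscaled_signal(
    design: SimulationDesign,
    terms: list[EffectTerm],
    G: np.ndarray,
    subj_idx: np.ndarray,
    std_time: np.ndarray,
) -> np.ndarray:
    S = np.zeros(subj_idx.size)
    for t in terms:
        if t.kind == MAIN:
            S += G[subj_idx, t.snp1]
        elif t.kind == EPISTATIC:
            S += G[subj_idx, t.snp1] * G[subj_idx, t.snp2]
        else:
            S += G[subj_idx, t.snp1] * std_time
    if _SETUPS[design.setup]["time_term"]:
        S += std_time
    return S


def calibrate_cg(
    h2: float, var_signal: float, var_re: float, sigma2: float
) -> float:
    """Scale constant: c_g = sqrt(h2 (V_re + sigma^2) / ((1 - h2) Var(S)))
    so that Var(c_g S) / (Var(c_g S) + V_re + sigma^2) = h2."""
    if h2 == 0.0:
        return 0.0
    if var_signal <= 0:
        raise ValueError("signal variance is zero; cannot calibrate heritability")
    return float(np.sqrt(h2 * (var_re + sigma2) / ((1.0 - h2) * var_signal)))


def gen_phenotypes(
    design: SimulationDesign,
    G: np.ndarray,
    times: list[np.ndarray],
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate trait values for given genotypes and observation times.

    Returns the long-format phenotype table and the ground-truth record
    (causal SNPs and terms, c_g, delta, psi, sigma^2, the realized random
    effects, and the realized heritability).
    """
    rng = np.random.default_rng(rng)
    n = G.shape[0]
    n_i = np.array([len(t) for t in times])
    subj_idx = np.repeat(np.arange(n), n_i)
    flat_times = np.concatenate(times)
    std_time = (flat_times - flat_times.mean()) / flat_times.std()

    causal = rng.choice(design.p, size=design.n_causal, replace=False)
    terms = _signal_terms(design, causal)
    S = _unscaled_signal(design, terms, G, subj_idx, std_time)

    grid = design.grid()
    W = np.vstack([build_interp_row(t, grid) for t in flat_times])
    factors = design.true_factors()
    D = reconstruct_D(factors)
    var_re = float(np.mean(np.einsum("ok,kl,ol->o", W, D, W)))

    c_g = calibrate_cg(design.h2, float(np.var(S)), var_re, design.sigma2)

    b = rng.standard_normal((n, design.k_true))
    nu = b @ factors.L().T
    re = np.einsum("ok,ok->o", W, nu[subj_idx])
    e = rng.normal(0.0, np.sqrt(design.sigma2), size=flat_times.size)
    y = c_g * S + re + e

    var_cs = float(np.var(c_g * S))
    var_total = var_cs + var_re + design.sigma2
    truth = {
        "design": design,
        "causal_snps": np.sort(causal),
        "causal_order": causal,
        "terms": terms,
        "c_g": c_g,
        "delta": factors.delta,
        "psi": factors.psi,
        "sigma2": design.sigma2,
        "b": b,
        "nu": nu,
        "grid": grid.points,
        "h2_target": design.h2,
        "h2_realized": var_cs / var_total if var_total > 0 else 0.0,
    }
    pheno = pd.DataFrame(
        {
            "subject_id": [f"s{idx:04d}" for idx in subj_idx],
            "time": flat_times,
            "value": y,
        }
    )
    return pheno, truth


def simulate(design: SimulationDesign, seed: int = 0) -> SimulatedData:
    """Full draw of one simulated dataset (genotypes, times, phenotypes).

    The same seed reproduces the identical dataset bit for bit.
    """
    rng = np.random.default_rng(seed)
    G, maf = gen_genotypes(design.n, design.p, design.maf_range, rng)
    times, _ = gen_times(design.n, design.N, rng=rng)
    pheno, truth = gen_phenotypes(design, G, times, rng)
    truth["maf"] = maf
    truth["seed"] = seed
    subjects = [f"s{i:04d}" for i in range(design.n)]
    geno = pd.DataFrame(
        G, index=pd.Index(subjects, name="subject_id"),
        columns=[f"snp{j:04d}" for j in range(design.p)],
    )
    return SimulatedData(genotypes=geno, phenotypes=pheno, truth=truth)
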