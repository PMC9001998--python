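"""Posterior summaries: inclusion probabilities, Bayes factors, 2log(BF)
genome profiles, HPD intervals, convergence diagnostics and ROC utilities.

The evidence that SNP position ``kappa_l`` matters is summarized by the Bayes
factor

    BF(kappa_l) = [P(kappa_l|y) / (1 - P(kappa_l|y))] /
                  [P(kappa_l) / (1 - P(kappa_l))],

where ``P(kappa_l|y)`` is the fraction of retained MCMC samples in which any
active effect (main, epistatic or SNP-covariate) involves that SNP — an
indicator per sample, so the probability is always in [0, 1] — and
``P(kappa_l)`` is the matching prior probability under the per-type inclusion
priors and the uniform position prior (complement rule over all terms that
touch the SNP).  Evidence categories follow the usual scale: weak for
3 < BF <= 10, moderate for 10 < BF <= 30, strong for BF > 30; profiles are
plotted as 2 log BF.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .effects import EPISTATIC, MAIN, SNP_COV
from .priors import PriorSpec
from .sampler import ChainResult

__all__ = [
    "inclusion_probability",
    "prior_inclusion_probability",
    "bayes_factor",
    "support_category",
    "genome_profile",
    "hpd_interval",
    "geweke_z",
    "gelman_rubin",
    "roc_curve",
    "tpr_at_fpr",
]

_KIND_GROUPS = {"main": (MAIN,), "epistatic": (EPISTATIC,), "snp_covariate": (SNP_COV,)}


def inclusion_probability(chain: ChainResult, snp: int) -> float:
    """Posterior probability that any active effect involves SNP ``snp``:
    per-sample indicator averaged over the chain (counted once per sample even
    when the SNP enters through several effects)."""
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    if not 0 <= snp < chain.p:
        raise ValueError(f"unknown SNP position {snp}")
    hits = 0
    for snap in chain.actives:
        if any(snp in term.snps for term, _ in snap):
            hits += 1
    return hits / chain.n_samples


def prior_inclusion_probability(priors: PriorSpec, p: int, q: int) -> float:
    """Prior probability that at least one active effect involves a given SNP
    under the independent Bernoulli(w_a) inclusion priors with uniform
    positions: complement rule over the 1 main, (p-1) epistatic and q
    SNP-covariate terms touching the SNP."""
    log_none = (
        math.log1p(-priors.w_main)
        + (p - 1) * math.log1p(-priors.w_epistatic)
        + q * math.log1p(-priors.w_snp_cov)
    )
    return -math.expm1(log_none)


def bayes_factor(posterior_prob: float, prior_prob: float) -> float:
    """Posterior odds over prior odds.  A posterior of exactly 1 yields +inf;
    degenerate priors (0 or 1) are rejected."""
    if not 0.0 < prior_prob < 1.0:
        raise ValueError("prior probability must be strictly inside (0, 1)")
    if not 0.0 <= posterior_prob <= 1.0:
        raise ValueError("posterior probability must be in [0, 1]")
    if posterior_prob == 1.0:
        return float("inf")
    post_odds = posterior_prob / (1.0 - posterior_prob)
    prior_odds = prior_prob / (1.0 - prior_prob)
    return post_odds / prior_odds


def support_category(bf: float) -> str:
    if bf > 30.0:
        return "strong"
    if bf > 10.0:
        return "moderate"
    if bf > 3.0:
        return "weak"
    return "none"


def genome_profile(
    chain: ChainResult,
    priors: Optional[PriorSpec] = None,
    snp_ids: Optional[Sequence[str]] = None,
    prior_prob: Optional[float] = None,
    per_type: bool = False,
) -> pd.DataFrame:
    """Per-SNP table of inclusion probability, BF, 2log(BF) and category for
    the combined (any-type) evidence, optionally with per-type columns.

    Zero posterior counts are floored at ``1/(2T)`` (continuity correction,
    flagged in the ``floored`` column) so the log profile stays finite.
    ``prior_prob`` overrides the complement-rule prior with a user scalar.
    """
    priors = priors if priors is not None else chain.priors
    T = chain.n_samples
    if T == 0:
        raise ValueError("empty chain")
    if prior_prob is None:
        prior_prob = prior_inclusion_probability(priors, chain.p, chain.q)
    floor = 1.0 / (2.0 * T)
    hits = chain.snp_hits()
    post = hits.mean(axis=0)
    floored = post < floor
    post_f = np.where(floored, floor, post)
    bf = np.array([bayes_factor(pp, prior_prob) for pp in post_f])
    table = pd.DataFrame(
        {
            "snp": snp_ids if snp_ids is not None else np.arange(chain.p),
            "position": np.arange(chain.p),
            "posterior": post,
            "prior": prior_prob,
            "bf": bf,
            "two_log_bf": 2.0 * np.log(bf),
            "category": [support_category(v) for v in bf],
            "floored": floored,
        }
    )
    if per_type:
        for name, kinds in _KIND_GROUPS.items():
            table[f"posterior_{name}"] = chain.snp_hits(kinds).mean(axis=0)
    return table


def hpd_interval(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` posterior mass (sorted-window
    method on the empirical sample)."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    m = max(1, int(math.ceil(level * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def geweke_z(trace: Sequence[float], first: float = 0.10, last: float = 0.50) -> float:
    """Geweke convergence Z-score comparing the means of the first ``first``
    and last ``last`` fractions of a trace, with segment standard errors
    corrected for autocorrelation via the effective sample size.  Returns NaN
    for a degenerate (constant) trace."""
    import arviz as az

    x = np.asarray(trace, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("trace too short for a Geweke diagnostic")
    a = x[: int(first * x.size)]
    b = x[-int(last * x.size) :]
    if np.var(a) == 0 or np.var(b) == 0:
        return float("nan")
    se = []
    for seg in (a, b):
        ess = float(az.ess(seg))
        ess = max(ess, 2.0)
        se.append(np.var(seg, ddof=1) / ess)
    return float((a.mean() - b.mean()) / math.sqrt(se[0] + se[1]))


def gelman_rubin(traces: Sequence[Sequence[float]]) -> float:
    """Gelman-Rubin potential scale reduction factor across >= 2 chains."""
    import arviz as az

    arr = np.asarray([np.asarray(t, dtype=float).ravel() for t in traces])
    if arr.shape[0] < 2:
        raise ValueError("need at least two chains for the PSRF")
    return float(az.rhat(az.convert_to_dataset(arr))["x"].values)


def roc_curve(scores: Sequence[float], truth: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points from sweeping a threshold over per-SNP scores."""
    from sklearn.metrics import roc_curve as _sk_roc

    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.sum() == 0:
        raise ValueError("no causal SNPs in the truth vector")
    finite = scores[np.isfinite(scores)]
    hi = finite.max() + 1.0 if finite.size else 1.0
    lo = finite.min() - 1.0 if finite.size else -1.0
    scores = np.clip(scores, lo, hi)  # +/-inf 2logBF ranks above/below all
    fpr, tpr, _ = _sk_roc(truth.astype(int), scores)
    return fpr, tpr


def tpr_at_fpr(scores, truth, max_fpr: float = 0.2) -> float:
    """Highest true-positive rate achieved at false-positive rate <= max_fpr
    (the truncated-ROC operating point used for power comparisons)."""
    fpr, tpr = roc_curve(scores, truth)
    ok = fpr <= max_fpr + 1e-12
    return float(tpr[ok].max()) if ok.any() else 0.0
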