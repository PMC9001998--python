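"""Results object returned by :meth:`LongitudinalGridModel.fit`.

Carries the thinned chain, exposes posterior summaries (means, medians,
standard deviations, 95% HPD intervals), per-SNP inclusion probabilities and
Bayes-factor genome profiles, convergence diagnostics, DIC/BPIC, and a
matplotlib profile plot.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import posterior as post
from .sampler import ChainResult

__all__ = ["MixedModelResults"]


class MixedModelResults:
    def __init__(self, model, chain: ChainResult, identifiability=None):
        self.model = model
        self.chain = chain
        self.identifiability = identifiability

    # ------------------------------------------------------------------ #
    # parameter summaries

    def _param_traces(self) -> dict[str, np.ndarray]:
        ch = self.chain
        traces = {"mu": ch.mu, "sigma2": ch.sigma2}
        for l in range(ch.delta.shape[1]):
            traces[f"delta{l + 1}"] = ch.delta[:, l]
        idx = 0
        k = ch.delta.shape[1]
        for m in range(2, k + 1):
            for l in range(1, m):
                traces[f"psi{m}{l}"] = ch.psi[:, idx]
                idx += 1
        for j, name in enumerate(self.model.covariate_names):
            traces[f"beta_{name}"] = ch.beta_cov[:, j]
        return traces

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, median, SD and HPD interval per model parameter."""
        rows = []
        for name, tr in self._param_traces().items():
            lo, hi = post.hpd_interval(tr, level)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(tr.mean()),
                    "median": float(np.median(tr)),
                    "sd": float(tr.std(ddof=1)),
                    f"hpd_{level:.0%}_low": lo,
                    f"hpd_{level:.0%}_high": hi,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def posterior_mean(self, name: str) -> float:
        return float(self._param_traces()[name].mean())

    def hpd(self, name: str, level: float = 0.95) -> tuple[float, float]:
        return post.hpd_interval(self._param_traces()[name], level)

    # ------------------------------------------------------------------ #
    # genetic-effect evidence

    def inclusion_probability(self, snp: int) -> float:
        return post.inclusion_probability(self.chain, snp)

    def prior_inclusion_probability(self) -> float:
        return post.prior_inclusion_probability(
            self.model.priors, self.model.p, self.model.q
        )

    def genome_profile(self, prior_prob: Optional[float] = None, per_type: bool = False) -> pd.DataFrame:
        return post.genome_profile(
            self.chain,
            self.model.priors,
            snp_ids=self.model.snp_ids,
            prior_prob=prior_prob,
            per_type=per_type,
        )

    # ------------------------------------------------------------------ #
    # model scores and diagnostics

    def dic(self) -> tuple[float, float]:
        from .selection import compute_dic

        return compute_dic(self.model, self.chain)

    def bpic(self) -> float:
        from .selection import compute_bpic

        return compute_bpic(self.model, self.chain)

    def geweke(self, first: float = 0.10, last: float = 0.50) -> pd.DataFrame:
        rows = []
        for name, tr in self._param_traces().items():
            try:
                z = post.geweke_z(tr, first, last)
            except ValueError:  # trace too short for the diagnostic
                z = float("nan")
            rows.append({"parameter": name, "z": z})
        return pd.DataFrame(rows).set_index("parameter")

    # ------------------------------------------------------------------ #
    # plotting

    def plot_profile(self, ax=None, per_type: bool = False):
        """Genome-wide 2log(BF) profile; causal-region spikes stand out
        against the floored background."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        prof = self.genome_profile(per_type=per_type)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        ax.plot(prof["position"], prof["two_log_bf"], lw=0.8, color="tab:red")
        for thr, lab in ((2 * np.log(3), "weak"), (2 * np.log(10), "moderate"), (2 * np.log(30), "strong")):
            ax.axhline(thr, ls=":", lw=0.6, color="grey")
        ax.set_xlabel("SNP position")
        ax.set_ylabel("2 log BF")
        return ax
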