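"""Candidate genetic effect terms and their design columns.

With ``p`` SNPs (additive 0/1/2 coding) and ``q`` always-included covariates
(standardized time first), the candidate effects are the ``p`` main effects,
the ``p(p-1)/2`` unordered SNP-SNP (epistatic) products, and the ``p*q``
SNP-covariate products, ``d = p + p(p-1)/2 + pq`` in total.  The catalog never
materializes columns for inactive terms: the sampler visits only a handful of
active effects at a time, so columns are built on demand from the genotype
matrix and the covariate block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

MAIN = "main"
EPISTATIC = "epistatic"
SNP_COV = "snp_covariate"

KINDS = (MAIN, EPISTATIC, SNP_COV)


@dataclass(frozen=True)
class EffectTerm:
    """One candidate effect: a main effect, an unordered SNP pair, or a
    SNP-by-covariate product."""

    kind: str
    snp1: int
    snp2: Optional[int] = None  # epistatic partner, snp1 < snp2
    cov: Optional[int] = None  # covariate index for snp_covariate terms

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == EPISTATIC:
            if self.snp2 is None or self.snp2 == self.snp1:
                raise ValueError("epistatic term needs two distinct SNPs")
            if self.snp1 > self.snp2:  # canonical unordered pair
                lo, hi = self.snp2, self.snp1
                object.__setattr__(self, "snp1", lo)
                object.__setattr__(self, "snp2", hi)
        if self.kind == SNP_COV and self.cov is None:
            raise ValueError("snp_covariate term needs a covariate index")

    @property
    def snps(self) -> tuple[int, ...]:
        return (self.snp1,) if self.snp2 is None else (self.snp1, self.snp2)


class EffectCatalog:
    """The ``d = p + p(p-1)/2 + pq`` candidate terms, indexable lazily."""

    def __init__(self, p: int, q: int):
        if p < 1 or q < 1:
            raise ValueError("need p >= 1 SNPs and q >= 1 covariates (time)")
        self.p = p
        self.q = q
        self.n_main = p
        self.n_epistatic = p * (p - 1) // 2
        self.n_snp_cov = p * q
        self.d = self.n_main + self.n_epistatic + self.n_snp_cov

    def count(self, kind: str) -> int:
        return {MAIN: self.n_main, EPISTATIC: self.n_epistatic, SNP_COV: self.n_snp_cov}[
            kind
        ]

    def term_from_index(self, idx: int) -> EffectTerm:
        """Canonical order: mains by SNP, pairs lexicographic, SNP x covariate
        by SNP then covariate."""
        if not 0 <= idx < self.d:
            raise IndexError(idx)
        if idx < self.n_main:
            return EffectTerm(MAIN, idx)
        idx -= self.n_main
        if idx < self.n_epistatic:
            # unrank lexicographic pair (i, j), i < j
            i = 0
            rem = idx
            while rem >= self.p - 1 - i:
                rem -= self.p - 1 - i
                i += 1
            return EffectTerm(EPISTATIC, i, i + 1 + rem)
        idx -= self.n_epistatic
        return EffectTerm(SNP_COV, idx // self.q, cov=idx % self.q)

    def index_of(self, term: EffectTerm) -> int:
        if term.kind == MAIN:
            return term.snp1
        if term.kind == EPISTATIC:
            i, j = term.snp1, term.snp2
            return self.n_main + (i * (2 * self.p - i - 1)) // 2 + (j - i - 1)
        return self.n_main + self.n_epistatic + term.snp1 * self.q + term.cov

    def terms(self) -> Iterator[EffectTerm]:
        for idx in range(self.d):
            yield self.term_from_index(idx)

    def random_term(self, kind: str, rng: np.random.Generator) -> EffectTerm:
        """Uniform draw over all terms of a kind without enumeration."""
        if kind == MAIN:
            return EffectTerm(MAIN, int(rng.integers(self.p)))
        if kind == EPISTATIC:
            i = int(rng.integers(self.p))
            j = int(rng.integers(self.p - 1))
            if j >= i:
                j += 1
            return EffectTerm(EPISTATIC, min(i, j), max(i, j))
        return EffectTerm(
            SNP_COV, int(rng.integers(self.p)), cov=int(rng.integers(self.q))
        )


def build_effect_catalog(p: int, q: int) -> EffectCatalog:
    return EffectCatalog(p, q)


def build_design_column(
    term: EffectTerm, G: np.ndarray, subj_idx: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Observation-level design column for one effect term.

    ``G`` is the ``n x p`` genotype matrix, ``subj_idx`` maps each of the
    ``N`` observations to its subject row, and ``C`` is the ``N x q``
    covariate block.  Epistatic columns are elementwise products of the two
    genotype columns; SNP-covariate columns multiply the genotype column by
    the covariate column.
    """
    g1 = G[subj_idx, term.snp1]
    if term.kind == MAIN:
        return g1.astype(float, copy=True)
    if term.kind == EPISTATIC:
        return g1 * G[subj_idx, term.snp2]
    return g1 * C[:, term.cov]


def build_design(
    G: np.ndarray,
    subj_idx: np.ndarray,
    C: np.ndarray,
    active_terms: list[EffectTerm],
) -> np.ndarray:
    """Columns for the active set only, preceded by the covariate block."""
    cols = [C] + [
        build_design_column(t, G, subj_idx, C)[:, None] for t in active_terms
    ]
    return np.hstack(cols)
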