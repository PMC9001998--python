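"""Identifiability of the grid-based covariance structure.

The marginal covariance of the stacked trait vector is ``P D P' + sigma^2 I_N``
with ``D = I_n (x) D``.  The pair ``(D, sigma^2)`` is identified exactly when
the homogeneous system ``P Dtilde P' + sigmatilde^2 I_N = 0`` has only the
trivial solution.  Collecting the distinct upper-triangular entries of that
system gives a linear system ``A X = 0`` in the unknowns
``X = (dtilde_11, dtilde_12, ..., dtilde_1k, dtilde_22, ..., dtilde_kk,
sigmatilde^2)``, where ``A`` has one row per within-subject observation pair
``(j, j')`` with ``j <= j'`` and its entries are polynomial in the
interpolation weights ``a_ijr``.  The model is identifiable iff
``rank(A) = k(k+1)/2 + 1``.

A canonical failure: all subjects observed exactly on the grid (every ``p_i``
the identity) leaves ``sigma^2`` confounded with the diagonal of ``D`` (rank
deficit one); a single off-grid observation restores full rank.  When the
design is non-identifiable one can instead fix ``sigma^2 = 0`` and model ``D``
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CoefficientSystem",
    "IdentifiabilityReport",
    "build_A",
    "is_identifiable",
    "required_rank",
    "resolve_nonidentifiable",
    "NonIdentifiableError",
]


class NonIdentifiableError(ValueError):
    """Raised when a design fails the rank criterion and no fix is requested."""


def _col_index(r: int, s: int, k: int) -> int:
    """Column of dtilde_{r,s} (0-based, r <= s) in the row-major upper triangle."""
    return r * k - r * (r - 1) // 2 + (s - r)


@dataclass(frozen=True)
class CoefficientSystem:
    """The coefficient matrix ``A`` of the identifiability system ``AX = 0``."""

    A: np.ndarray
    k: int

    @property
    def n_unknowns(self) -> int:
        return self.k * (self.k + 1) // 2 + 1


def required_rank(k: int) -> int:
    return k * (k + 1) // 2 + 1


def build_A(interp_matrices: Sequence[np.ndarray]) -> CoefficientSystem:
    """Assemble ``A`` from per-subject interpolation matrices.

    For subject ``i`` and observation pair ``j <= j'``, the row's coefficient
    on ``dtilde_{r,s}`` (``r <= s``) is ``a_ijr a_ij's + [r != s] a_ijs a_ij'r``
    and the coefficient on ``sigmatilde^2`` is ``1`` iff ``j = j'``.  Rows are
    stacked subject by subject, pairs in row-major upper-triangular order;
    duplicate rows are retained so the row count equals
    ``sum_i n_i (n_i + 1) / 2``.
    """
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in interp_matrices]
    if not mats:
        raise ValueError("need at least one subject")
    k = mats[0].shape[1]
    if any(m.shape[1] != k for m in mats):
        raise ValueError("all subjects must share the same number of grid points k")
    ncols = required_rank(k)
    rows = []
    for p in mats:
        ni = p.shape[0]
        for j in range(ni):
            for jp in range(j, ni):
                row = np.zeros(ncols)
                for r in range(k):
                    for s in range(r, k):
                        c = p[j, r] * p[jp, s]
                        if r != s:
                            c += p[j, s] * p[jp, r]
                        row[_col_index(r, s, k)] = c
                if j == jp:
                    row[-1] = 1.0
                rows.append(row)
    return CoefficientSystem(np.vstack(rows), k)


@dataclass(frozen=True)
class IdentifiabilityReport:
    identifiable: bool
    rank: int
    required: int
    n_rows: int
    k: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "identifiable" if self.identifiable else "NOT identifiable"
        return (
            f"k={self.k}: rank(A) = {self.rank}, required = {self.required} "
            f"({self.n_rows} equations) -> {verdict}"
        )


def is_identifiable(system: CoefficientSystem) -> IdentifiabilityReport:
    """Rank verdict for a built coefficient system.

    The rank uses singular values with numpy's default tolerance
    ``max(A.shape) * eps * sigma_max``; the interpolation weights are simple
    rationals, so this is far below any genuine singular-value gap.
    """
    rank = int(np.linalg.matrix_rank(system.A))
    req = required_rank(system.k)
    return IdentifiabilityReport(
        identifiable=rank == req,
        rank=rank,
        required=req,
        n_rows=system.A.shape[0],
        k=system.k,
    )


def check_design(interp_matrices: Sequence[np.ndarray]) -> IdentifiabilityReport:
    """Convenience: build ``A`` and apply the rank criterion."""
    return is_identifiable(build_A(interp_matrices))


def resolve_nonidentifiable(
    report: IdentifiabilityReport, fix_sigma2: bool = False
) -> dict:
    """Decide how to proceed with a (possibly) non-identifiable design.

    Returns a model-adjustment dict ``{"fix_sigma2": bool}``.  An identifiable
    design is a no-op.  A non-identifiable design either raises
    :class:`NonIdentifiableError` or, with ``fix_sigma2=True``, freezes the
    residual variance at zero so that ``D`` is modelled directly.
    """
    if report.identifiable:
        return {"fix_sigma2": False}
    if fix_sigma2:
        return {"fix_sigma2": True}
    raise NonIdentifiableError(
        f"design is not identifiable: rank(A) = {report.rank} < "
        f"{report.required} required (deficit {report.required - report.rank}). "
        "Add off-grid observations, reduce k, or pass fix_sigma2=True to "
        "freeze sigma^2 at 0 and model D directly."
    )
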