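"""Grid placement, linear-interpolation weights, and the modified Cholesky
reconstruction of the random-effect covariance.

The within-subject dependence of a longitudinal trait is modelled through a
``k``-vector of random effects defined at pre-specified grid time points.  An
observation at time ``t`` between grid points ``t_r`` and ``t_{r+1}`` loads on
those two points with linear-interpolation weights
``((t_{r+1}-t)/(t_{r+1}-t_r), (t-t_r)/(t_{r+1}-t_r))``; an observation exactly
on a grid point loads on it with weight one.  Stacking the per-observation
weight rows gives the subject matrix ``p_i`` (``n_i x k``) and the
block-diagonal ``P = diag(p_1, ..., p_n)``.

The grid-level covariance ``D`` is parameterised by its modified Cholesky
decomposition ``D = Delta Psi Psi' Delta`` with ``Delta = diag(delta)``,
``delta_l >= 0``, and ``Psi`` unit lower triangular, which admits conjugate
half-normal / normal priors on ``delta`` and ``psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "CholeskyFactors",
    "default_grid",
    "build_interp_row",
    "build_interp_matrix",
    "psi_matrix",
    "psi_vector",
    "reconstruct_D",
]


@dataclass(frozen=True)
class GridSpec:
    """An ordered set of ``k`` grid time points.

    Parameters
    ----------
    points : array-like
        Strictly increasing time values ``(t_1, ..., t_k)``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).ravel()
        if pts.size < 1:
            raise ValueError("grid needs at least one point")
        if pts.size > 1 and not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def k(self) -> int:
        return self.points.size

    def covers(self, times: np.ndarray) -> bool:
        t = np.asarray(times, dtype=float)
        return bool(t.min() >= self.points[0] and t.max() <= self.points[-1])


def default_grid(times: Sequence[float], k: int) -> GridSpec:
    """Equally spaced grid of ``k`` points spanning the observed time range."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    t = np.asarray(times, dtype=float)
    lo, hi = float(t.min()), float(t.max())
    if lo == hi:
        if k != 1:
            raise ValueError("all observation times identical: only k=1 is meaningful")
        return GridSpec(np.array([lo]))
    if k == 1:
        raise ValueError("k=1 cannot cover a non-degenerate time range")
    return GridSpec(np.linspace(lo, hi, k))


def build_interp_row(t: float, grid: GridSpec) -> np.ndarray:
    """Linear-interpolation weight row ``p_ij`` (length ``k``) for time ``t``.

    The row sums to one, has entries in [0, 1], and at most two adjacent
    nonzeros.  ``t`` exactly on a grid point yields the unit vector for that
    point.  No extrapolation: ``t`` outside ``[t_1, t_k]`` raises.
    """
    pts = grid.points
    t = float(t)
    if t < pts[0] or t > pts[-1]:
        raise ValueError(
            f"time {t} outside grid span [{pts[0]}, {pts[-1]}]; extend the grid"
        )
    row = np.zeros(grid.k)
    # side='right' - 1 gives the left bracketing point; exact hits land on it.
    r = int(np.searchsorted(pts, t, side="right")) - 1
    if r == grid.k - 1 or t == pts[r]:
        row[r] = 1.0
        return row
    h = pts[r + 1] - pts[r]
    w = (t - pts[r]) / h
    row[r] = 1.0 - w
    row[r + 1] = w
    return row


def build_interp_matrix(
    times_by_subject: Sequence[Sequence[float]], grid: GridSpec
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-subject interpolation matrices and the block-diagonal ``P``.

    Returns
    -------
    mats : list of ndarray
        One ``n_i x k`` matrix per subject, rows from :func:`build_interp_row`.
    P : ndarray
        The ``N x nk`` block-diagonal assembly ``diag(p_1, ..., p_n)``.
    """
    mats = []
    for times in times_by_subject:
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            raise ValueError("every subject needs at least one observation")
        mats.append(np.vstack([build_interp_row(t, grid) for t in times]))
    n = len(mats)
    N = sum(m.shape[0] for m in mats)
    P = np.zeros((N, n * grid.k))
    row = 0
    for i, m in enumerate(mats):
        P[row : row + m.shape[0], i * grid.k : (i + 1) * grid.k] = m
        row += m.shape[0]
    return mats, P


def _n_psi(k: int) -> int:
    return k * (k - 1) // 2


def psi_matrix(psi: Sequence[float], k: int) -> np.ndarray:
    """Unit-lower-triangular ``Psi`` from the vector ``(psi_ml: m=2..k, l<m)``.

    The vector is ordered row by row: ``psi_21, psi_31, psi_32, psi_41, ...``.
    """
    psi = np.asarray(psi, dtype=float).ravel()
    if psi.size != _n_psi(k):
        raise ValueError(f"psi must have k(k-1)/2 = {_n_psi(k)} entries, got {psi.size}")
    P = np.eye(k)
    idx = 0
    for m in range(1, k):
        P[m, :m] = psi[idx : idx + m]
        idx += m
    return P


def psi_vector(Psi: np.ndarray) -> np.ndarray:
    """Strict lower triangle of ``Psi``, row by row (inverse of psi_matrix)."""
    Psi = np.asarray(Psi, dtype=float)
    k = Psi.shape[0]
    return np.concatenate([Psi[m, :m] for m in range(1, k)]) if k > 1 else np.empty(0)


@dataclass(frozen=True)
class CholeskyFactors:
    """Modified Cholesky factors ``(delta, psi)`` of ``D = Delta Psi Psi' Delta``."""

    delta: np.ndarray
    psi: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float).ravel()
        if np.any(d < 0):
            raise ValueError("delta entries must be nonnegative")
        p = np.asarray(self.psi, dtype=float).ravel()
        if p.size != _n_psi(d.size):
            raise ValueError(
                f"psi must have k(k-1)/2 = {_n_psi(d.size)} entries, got {p.size}"
            )
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "psi", p)

    @property
    def k(self) -> int:
        return self.delta.size

    def psi_matrix(self) -> np.ndarray:
        return psi_matrix(self.psi, self.k)

    def L(self) -> np.ndarray:
        """The lower-triangular factor ``L = Delta Psi`` with ``D = L L'``."""
        return self.delta[:, None] * self.psi_matrix()


def reconstruct_D(factors: CholeskyFactors | tuple) -> np.ndarray:
    """Rebuild ``D = Delta Psi Psi' Delta`` from its factors.

    Accepts a :class:`CholeskyFactors` or a ``(delta, psi)`` pair; ``psi`` may
    be given as the stacked vector or as a full unit-lower-triangular matrix.
    """
    if not isinstance(factors, CholeskyFactors):
        delta, psi = factors
        psi = np.asarray(psi, dtype=float)
        if psi.ndim == 2:
            psi = psi_vector(psi)
        factors = CholeskyFactors(np.asarray(delta, dtype=float), psi)
    L = factors.L()
    return L @ L.T
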