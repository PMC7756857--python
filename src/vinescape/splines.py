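"""Natural cubic regression splines with a curvature penalty.

The smooth terms in the outbreak / spray models use a low-rank cubic
regression spline: basis functions are the natural cubic interpolants of
indicator data at ``k`` quantile knots (the "cardinal" or value
parameterisation), and the wiggliness penalty is the exact integrated
squared second derivative of the interpolant.  With the basis dimension
capped at ``k = 3`` each smooth contributes two effective columns after the
sum-to-zero identifiability constraint, which is what keeps the fitted
landscape responses simple and guards against overfitting.

For knots xi_1 < ... < xi_k with gaps h_j = xi_{j+1} - xi_j, the band
matrices ``D`` ((k-2) x k) and ``B`` ((k-2) x (k-2)) relate knot values to
second derivatives at the interior knots (natural boundary conditions), and
the penalty is ``S = D' B^{-1} D``.  Outside the knot range the basis
extrapolates linearly, as a natural spline does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CubicRegressionSpline", "SplineBasis", "build_spline_basis"]


def _crs_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (F, S): knot-values -> second-derivative map, and penalty."""
    k = len(knots)
    h = np.diff(knots)
    if k == 2:
        return np.zeros((2, 2)), np.zeros((2, 2))
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    F = np.zeros((k, k))
    F[1:-1, :] = Binv_D  # natural BC: zero curvature at end knots
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0
    return F, S


class CubicRegressionSpline:
    """Cardinal natural cubic spline basis on fixed knots.

    ``matrix(x)[i, j]`` is the value at ``x[i]`` of the natural cubic spline
    interpolating the indicator vector ``e_j`` at the knots.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self.F, self.penalty = _crs_matrices(knots)

    @property
    def k(self) -> int:
        return len(self.knots)

    def matrix(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xi, F, k = self.knots, self.F, self.k
        h = np.diff(xi)
        X = np.zeros((len(x), k))

        inside = (x >= xi[0]) & (x <= xi[-1])
        if np.any(inside):
            xv = x[inside]
            j = np.clip(np.searchsorted(xi, xv, side="right") - 1, 0, k - 2)
            hj = h[j]
            am = (xi[j + 1] - xv) / hj
            ap = (xv - xi[j]) / hj
            cm = ((xi[j + 1] - xv) ** 3 / hj - hj * (xi[j + 1] - xv)) / 6.0
            cp = ((xv - xi[j]) ** 3 / hj - hj * (xv - xi[j])) / 6.0
            rows = np.zeros((len(xv), k))
            rows[np.arange(len(xv)), j] += am
            rows[np.arange(len(xv)), j + 1] += ap
            rows += cm[:, None] * F[j, :] + cp[:, None] * F[j + 1, :]
            X[inside] = rows

        # linear extrapolation with the boundary slope of the natural spline
        left = x < xi[0]
        if np.any(left):
            e = np.zeros(k)
            e[0], e[1] = -1.0 / h[0], 1.0 / h[0]
            slope = e - h[0] * (2.0 * F[0, :] + F[1, :]) / 6.0
            val0 = np.zeros(k)
            val0[0] = 1.0
            X[left] = val0 + np.outer(x[left] - xi[0], slope)
        right = x > xi[-1]
        if np.any(right):
            e = np.zeros(k)
            e[-2], e[-1] = -1.0 / h[-1], 1.0 / h[-1]
            slope = e + h[-1] * (F[-2, :] + 2.0 * F[-1, :]) / 6.0
            valk = np.zeros(k)
            valk[-1] = 1.0
            X[right] = valk + np.outer(x[right] - xi[-1], slope)
        return X


@dataclass
class SplineBasis:
    """A fitted-data spline basis with the sum-to-zero constraint absorbed.

    ``X`` (n x (k-1)) and ``S`` ((k-1) x (k-1)) are the constrained design
    and penalty; ``matrix`` reproduces constrained basis columns at new x.
    """

    spline: CubicRegressionSpline
    Z: np.ndarray  # k x (k-1) null-space transform of the constraint
    X: np.ndarray
    S: np.ndarray
    colmeans: np.ndarray

    @property
    def ncol(self) -> int:
        return self.Z.shape[1]

    def matrix(self, x) -> np.ndarray:
        return self.spline.matrix(x) @ self.Z

    @property
    def penalty_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.S)) if self.S.size else 0


def build_spline_basis(x, k: int = 3) -> SplineBasis:
    """Build a constrained cubic regression spline basis on data ``x``.

    Knots sit at evenly spaced quantiles of the distinct values of ``x``.
    If fewer than ``k`` distinct values exist, ``k`` is reduced with a
    warning; a constant ``x`` is an error.  The sum-to-zero constraint
    (columns of the raw basis average to zero over the data) is absorbed by
    reparameterising onto the constraint null space, dropping one column.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError("basis dimension k must be >= 2")
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("cannot build a spline basis on a constant covariate")
    if len(uniq) < k:
        warnings.warn(
            f"only {len(uniq)} distinct covariate values; reducing basis "
            f"dimension from {k} to {len(uniq)}",
            stacklevel=2,
        )
        k = len(uniq)
    qs = np.linspace(0, 1, k)
    knots = np.quantile(uniq, qs)
    # guard against duplicate quantile knots on skewed data
    knots = np.unique(knots)
    if len(knots) < k:
        knots = np.linspace(uniq[0], uniq[-1], k)
    spline = CubicRegressionSpline(knots)
    Xraw = spline.matrix(x)
    m = Xraw.mean(axis=0)
    # orthonormal null space of the constraint row m'
    _, _, Vt = np.linalg.svd(m[None, :])
    Z = Vt[1:, :].T
    X = Xraw @ Z
    S = Z.T @ spline.penalty @ Z
    S = (S + S.T) / 2.0
    return SplineBasis(spline=spline, Z=Z, X=X, S=S, colmeans=m)
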