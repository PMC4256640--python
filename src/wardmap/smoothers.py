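"""P-spline building blocks: B-spline bases and random-walk difference penalties.

A Bayesian P-spline models a smooth effect f(x) = B(x) gamma with a
random-walk prior on adjacent coefficients; the prior precision is
K = D_r' D_r / tau^2 where D_r is the r-th order difference matrix.  K is
rank-deficient (nullspace = polynomials of degree r-1), so the smooth is
identified by centring its coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "bspline_basis", "rw_penalty", "difference_matrix"]


@dataclass(frozen=True)
class SplineBasis:
    """Evaluated B-spline basis with its random-walk penalty."""

    knots: np.ndarray  # full knot vector incl. replicated boundary knots
    degree: int
    B: np.ndarray  # (n, K) basis matrix
    K_pen: np.ndarray  # (K, K) penalty D'D
    penalty_order: int

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix at new points inside the knot domain."""
        return BSpline.design_matrix(np.asarray(x, dtype=float), self.knots, self.degree).toarray()


def difference_matrix(K: int, order: int) -> np.ndarray:
    """The order-th difference matrix D of shape (K - order, K)."""
    if order < 1:
        raise ValueError("difference order must be >= 1")
    if K <= order:
        raise ValueError(f"need K > order, got K={K}, order={order}")
    return np.diff(np.eye(K), n=order, axis=0)


def rw_penalty(K: int, order: int = 2) -> np.ndarray:
    """Random-walk penalty D'D for a coefficient vector of length K.

    ``beta' (D'D) beta`` equals the sum of squared order-th differences of
    beta; the nullspace has dimension ``order`` (constants for order 1,
    constants and linear trends for order 2).
    """
    if order not in (1, 2):
        raise ValueError("penalty order must be 1 or 2")
    D = difference_matrix(K, order)
    return D.T @ D


def bspline_basis(
    x,
    n_inner_knots: int = 20,
    degree: int = 3,
    penalty_order: int = 2,
) -> SplineBasis:
    """Equidistant-knot B-spline basis evaluated at ``x``.

    ``n_inner_knots`` is the number of equal-width intervals spanning
    [min(x), max(x)]; with ``degree``-fold replicated boundary knots this
    gives K = n_inner_knots + degree basis functions (Cox–de Boor).  The
    penalty order is capped at K - 1 so small bases remain penalizable.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D vector with at least 2 points")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("x is constant: no domain to place knots on")
    if n_inner_knots < 1:
        raise ValueError("n_inner_knots must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    breakpoints = np.linspace(lo, hi, n_inner_knots + 1)
    knots = np.r_[np.repeat(lo, degree), breakpoints, np.repeat(hi, degree)]
    B = BSpline.design_matrix(x, knots, degree).toarray()
    K = B.shape[1]
    assert K == n_inner_knots + degree
    penalty_order = min(penalty_order, K - 1)
    if penalty_order < 1:  # single basis function: nothing to penalize
        K_pen = np.zeros((K, K))
        penalty_order = 0
    else:
        K_pen = rw_penalty(K, penalty_order)
    return SplineBasis(knots=knots, degree=degree, B=B, K_pen=K_pen, penalty_order=penalty_order)
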