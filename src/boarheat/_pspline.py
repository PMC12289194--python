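"""Penalized-regression-spline building blocks (P-splines).

Cubic B-spline bases on equally spaced knots with second-order difference
penalties, a wrap-around (cyclic) variant for periodic covariates such as
hour of day, and tensor-product interaction bases built as row-wise
Kronecker products of sum-to-zero-constrained marginals.  Constraining the
marginals first means the tensor term spans pure interactions only (no
main-effect leakage), mirroring how interaction smooths are constructed in
mainstream GAM software.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "bspline_design",
    "cyclic_design",
    "diff_penalty",
    "cyclic_diff_penalty",
    "sum_to_zero",
    "row_kron",
]

DEGREE = 3


def bspline_design(x: np.ndarray, lo: float, hi: float, k: int) -> np.ndarray:
    """Dense cubic B-spline design with ``k`` basis functions on [lo, hi].

    Values outside [lo, hi] are clamped to the boundary (constant
    extrapolation of the boundary basis values).
    """
    if k < 4:
        raise ValueError("need at least 4 cubic B-spline basis functions")
    if hi <= lo:
        hi = lo + 1.0
    h = (hi - lo) / (k - DEGREE)
    knots = lo + h * np.arange(-DEGREE, k + 1)
    xc = np.clip(np.asarray(x, dtype=float), lo, hi - 1e-12 * (hi - lo))
    return BSpline.design_matrix(xc, knots, DEGREE).toarray()


def cyclic_design(x: np.ndarray, period: float, k: int) -> np.ndarray:
    """Cyclic cubic B-spline design: ``k`` basis functions, period-periodic.

    Built from an ordinary basis on uniform knots over one period, with the
    three overhanging columns folded back modulo ``k``; on uniform knots the
    folded basis and all its derivatives match at the period ends.
    """
    if k < 4:
        raise ValueError("need at least 4 cyclic basis functions")
    h = period / k
    knots = h * np.arange(-DEGREE, k + DEGREE + 1)
    xm = np.mod(np.asarray(x, dtype=float), period)
    big = BSpline.design_matrix(xm, knots, DEGREE).toarray()  # k + 3 columns
    out = np.zeros((big.shape[0], k))
    for j in range(big.shape[1]):
        out[:, j % k] += big[:, j]
    return out


def diff_penalty(k: int, order: int = 2) -> np.ndarray:
    """S = D'D with D the ``order``-th difference matrix on k coefficients."""
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def cyclic_diff_penalty(k: int, order: int = 2) -> np.ndarray:
    """Difference penalty with wrap-around (coefficients on a circle)."""
    rows = []
    for i in range(k):
        r = np.zeros(k)
        if order == 2:
            r[(i - 1) % k] = 1.0
            r[i] += -2.0
            r[(i + 1) % k] = 1.0
        else:
            r[i] = -1.0
            r[(i + 1) % k] = 1.0
        rows.append(r)
    d = np.array(rows)
    return d.T @ d


def sum_to_zero(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the column-sum constraint.

    Reparameterising a smooth as ``X @ Z`` makes it orthogonal to the
    intercept over the training data (removes the confounded constant).
    """
    c = X.sum(axis=0, keepdims=True)
    q, _ = np.linalg.qr(c.T, mode="complete")
    return q[:, 1:]


def row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product for tensor smooths."""
    n = a.shape[0]
    return np.einsum("ni,nj->nij", a, b).reshape(n, -1)
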