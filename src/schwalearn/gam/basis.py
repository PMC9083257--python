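"""B-spline bases, difference penalties and tensor-product blocks."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from ..errors import DomainError


def bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3,
                  domain: Tuple[float, float] | None = None) -> np.ndarray:
    """Clamped (open-uniform) B-spline basis over [min(x), max(x)].

    Rows sum to 1 (partition of unity). Boundary knots are repeated, so for
    ``n_basis == degree + 1`` the basis reduces to the Bernstein polynomials.
    Evaluation points outside the domain are clamped to its edge (used when
    predicting on new data near the boundary).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("x must be finite")
    if n_basis < degree + 1:
        raise DomainError(f"n_basis must be >= degree + 1, got {n_basis}")
    if domain is None:
        lo, hi = float(x.min()), float(x.max())
    else:
        lo, hi = map(float, domain)
    if not hi > lo:
        raise DomainError("constant x: cannot place spline knots")
    knots = np.concatenate([
        np.repeat(lo, degree),
        np.linspace(lo, hi, n_basis - degree + 1),
        np.repeat(hi, degree),
    ])
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, knots, degree).toarray()
    return B


def greville_abscissae(n_basis: int, degree: int,
                       domain: Tuple[float, float]) -> np.ndarray:
    """Greville sites of the clamped basis: coefficient sequences linear in
    these sites reproduce linear functions of x."""
    lo, hi = domain
    knots = np.concatenate([
        np.repeat(lo, degree),
        np.linspace(lo, hi, n_basis - degree + 1),
        np.repeat(hi, degree),
    ])
    return np.array([knots[i + 1: i + degree + 1].mean()
                     for i in range(n_basis)])


def difference_penalty(n_basis: int, order: int = 2,
                       points: np.ndarray | None = None) -> np.ndarray:
    """S = D'D with D an ``order``-th difference operator.

    With ``points`` given (the Greville sites of a clamped basis), divided
    differences with respect to those sites are used, so the penalty null
    space consists of coefficient sequences representing polynomials of
    degree < order in x (for order 2: exactly the affine functions).
    """
    if points is None:
        D = np.diff(np.eye(n_basis), n=order, axis=0)
        return D.T @ D
    g = np.asarray(points, float)
    if g.shape != (n_basis,):
        raise DomainError("points must have length n_basis")
    D = np.eye(n_basis)
    for _ in range(order):
        m = D.shape[0]
        step = n_basis - m + 1  # span of the divided difference at this level
        W = np.zeros((m - 1, m))
        for i in range(m - 1):
            W[i, i] = -1.0 / (g[i + step] - g[i])
            W[i, i + 1] = 1.0 / (g[i + step] - g[i])
        D = W @ D
    return D.T @ D


def sum_to_zero_constraint(block: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the column-mean constraint.

    Reparameterizing a smooth block X as X @ Z absorbs the identifiability
    constraint sum_i f(x_i) = 0, removing one coefficient."""
    c = block.mean(axis=0, keepdims=True)
    Z = null_space(c)
    if Z.shape[1] != block.shape[1] - 1:
        raise DomainError("degenerate constraint: smooth block has zero mean "
                          "columns only")
    return Z


def row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product."""
    n = a.shape[0]
    if b.shape[0] != n:
        raise DomainError("marginal bases must have the same number of rows")
    return np.einsum("ij,ik->ijk", a, b).reshape(n, a.shape[1] * b.shape[1])


def tensor_term(marginals: Sequence[np.ndarray],
                penalties: Sequence[np.ndarray],
                partial: bool = False
                ) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Tensor-product design block and Kronecker-expanded penalties.

    With ``partial=True`` each marginal is first sum-to-zero centred and the
    resulting interaction block is explicitly orthogonalized against both
    centred marginal main-effect blocks, yielding the interaction-only
    ("ti"-style) smooth.
    """
    if len(marginals) != 2 or len(penalties) != 2:
        raise DomainError("tensor_term expects exactly two marginals")
    B1, B2 = (np.asarray(m, float) for m in marginals)
    S1, S2 = (np.asarray(s, float) for s in penalties)
    if S1.shape[0] != B1.shape[1] or S2.shape[0] != B2.shape[1]:
        raise DomainError("penalty dimensions do not match marginal bases")
    if partial:
        Z1 = sum_to_zero_constraint(B1)
        Z2 = sum_to_zero_constraint(B2)
        B1c, B2c = B1 @ Z1, B2 @ Z2
        S1c, S2c = Z1.T @ S1 @ Z1, Z2.T @ S2 @ Z2
        T = row_kron(B1c, B2c)
        M = np.hstack([B1c, B2c])
        A, *_ = np.linalg.lstsq(M, T, rcond=None)
        T = T - M @ A
        pens = [np.kron(S1c, np.eye(B2c.shape[1])),
                np.kron(np.eye(B1c.shape[1]), S2c)]
        return T, pens
    T = row_kron(B1, B2)
    pens = [np.kron(S1, np.eye(B2.shape[1])),
            np.kron(np.eye(B1.shape[1]), S2)]
    return T, pens
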