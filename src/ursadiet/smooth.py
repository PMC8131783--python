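"""Low-rank thin-plate regression spline basis for one covariate.

The full 1-D thin-plate spline (order m = 2) represents a smooth as
f(x) = sum_j delta_j |x - x_j|^3 + a0 + a1 x with wiggliness penalty
delta' E delta, E_ij = |x_i - x_j|^3, subject to the side conditions
T' delta = 0 with T = [1, x]. The low-rank version truncates delta to
the leading eigenspace of E, giving a k-dimensional basis whose penalty
null space is exactly the linear functions: a straight line is never
penalized, so under heavy smoothing the fit collapses to a line rather
than a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space


class BasisConfigurationError(ValueError):
    pass


def _eta(r: np.ndarray) -> np.ndarray:
    return np.abs(r) ** 3


@dataclass(frozen=True)
class SmoothBasis:
    """A fitted-ready spline basis: evaluate with :meth:`design`,
    penalize with :attr:`penalty`.

    Attributes
    ----------
    knots : the covariate values the radial basis is anchored on.
    projector : maps the radial-basis evaluations to the k - 2
        penalized columns (eigenvector truncation with the side
        conditions absorbed).
    penalty : (k x k) positive-semidefinite penalty; its null space is
        the last two (constant and linear) columns.
    """

    knots: np.ndarray
    projector: np.ndarray  # (m_knots, k-2)
    penalty: np.ndarray  # (k, k)
    k: int
    null_dim: int = 2

    def design(self, x) -> np.ndarray:
        """Evaluate the k basis functions at ``x`` (any values, including
        off-knot points for prediction)."""
        x = np.asarray(x, dtype=float).ravel()
        E = _eta(x[:, None] - self.knots[None, :])
        return np.column_stack([E @ self.projector, np.ones_like(x), x])


def build_tprs_basis(x, k: int = 5) -> SmoothBasis:
    """Construct the rank-k thin-plate regression spline basis on the
    unique values of ``x``.

    ``k`` counts all basis functions including the two-dimensional
    linear null space; it is silently capped at the number of distinct
    covariate values.
    """
    if k < 3:
        raise BasisConfigurationError(f"k = {k}: need at least 3 basis functions")
    x = np.asarray(x, dtype=float).ravel()
    knots = np.unique(x)
    if knots.size < 3:
        raise BasisConfigurationError("need at least 3 distinct covariate values")
    k = min(k, knots.size)

    E = _eta(knots[:, None] - knots[None, :])
    T = np.column_stack([np.ones_like(knots), knots])
    eigval, eigvec = np.linalg.eigh(E)
    order = np.argsort(-np.abs(eigval))
    U = eigvec[:, order[:k]]
    lam = eigval[order[:k]]

    # Absorb the side conditions T' U z = 0 into the truncated space.
    Z = null_space(T.T @ U)  # (k, k-2)
    projector = U @ Z
    S_pen = Z.T @ (lam[:, None] * Z)  # Z' diag(lam) Z, conditionally PSD
    S_pen = (S_pen + S_pen.T) / 2.0
    w, V = np.linalg.eigh(S_pen)
    S_pen = (V * np.clip(w, 0.0, None)) @ V.T  # clip round-off negatives

    S = np.zeros((k, k))
    S[: k - 2, : k - 2] = S_pen
    return SmoothBasis(knots=knots, projector=projector, penalty=S, k=k)


def center_block(X: np.ndarray, S: np.ndarray, rows=None):
    """Absorb the sum-to-zero identifiability constraint over ``rows``.

    Returns (X @ Q, Q' S Q, Q) where Q spans the null space of the
    constraint ``sum over rows of X beta = 0``. The constant direction
    leaves the penalty null space; one unpenalized (linear) direction
    remains.
    """
    c = X.sum(axis=0) if rows is None else X[rows].sum(axis=0)
    norm = np.linalg.norm(c)
    if norm == 0:
        return X, S, np.eye(X.shape[1])
    Q = null_space(c[None, :] / norm)
    SQ = Q.T @ S @ Q
    SQ = (SQ + SQ.T) / 2.0
    return X @ Q, SQ, Q
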