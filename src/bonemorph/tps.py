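"""Thin-plate splines in 3D: warps and bending energy.

Uses the 3D radial kernel U(r) = -r.  The bending-energy quadratic form is
conditionally positive semidefinite on the space orthogonal to affine
transforms, so TPS warps reproduce affine maps exactly with zero bending
energy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["TPSWarp", "bending_energy_matrix", "bending_energy"]


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return -cdist(a, b)


def bending_energy_matrix(reference: np.ndarray, reg: float = 1e-10) -> np.ndarray:
    """Bending-energy matrix L_k of a reference configuration (k, 3).

    The energy of a target y (per coordinate) is ``y^T B y`` with
    ``B = L_k`` the upper-left block of the inverse of the bordered TPS
    system; B annihilates affine functions of the reference.
    """
    x = np.asarray(reference, dtype=float)
    k = len(x)
    K = _kernel(x, x) + reg * np.eye(k)
    P = np.column_stack([np.ones(k), x])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)


def bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """Total TPS bending energy of the map reference -> target (sum over
    the three coordinates)."""
    B = bending_energy_matrix(reference)
    y = np.asarray(target, dtype=float)
    return float(np.einsum("id,ij,jd->", y, B, y))


class TPSWarp:
    """TPS interpolating warp from source to target landmarks (k >= 4,
    non-coplanar)."""

    def __init__(self, source: np.ndarray, target: np.ndarray, reg: float = 1e-10):
        x = np.asarray(source, dtype=float)
        y = np.asarray(target, dtype=float)
        if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
            raise ValueError("source/target must both be (k, 3)")
        k = len(x)
        if k < 4:
            raise ValueError("TPS needs at least 4 landmarks")
        if np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-9) < 3:
            raise ValueError("degenerate (coplanar) source landmarks")
        K = _kernel(x, x) + reg * np.eye(k)
        P = np.column_stack([np.ones(k), x])
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = y
        sol = np.linalg.solve(L, rhs)
        self.source = x
        self.weights = sol[:k]
        self.affine = sol[k:]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        U = _kernel(p, self.source)
        Pq = np.column_stack([np.ones(len(p)), p])
        return U @ self.weights + Pq @ self.affine
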