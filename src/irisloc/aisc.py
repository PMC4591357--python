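"""Affine-invariant shape-constraint (AISC) eye-center selection.

An eye-center landmark m_c is expressed as a linear combination of k
neighboring landmarks (eye contour + eyebrow): m_c' = M' @ omega_c.
With the weights constrained to sum to one the combination is affine —
for any affine map A, A(m_c') = (A M') @ omega_c — so weights fitted on
training shapes reconstruct the center correctly under any pose the
aligner produces. The candidate isocenter nearest the reconstruction is
selected as the final eye center; an empty candidate set falls back to
the reconstruction itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import CandidateSet
from .shapes import LANDMARK_SCHEME_29

__all__ = [
    "NeighborBasis",
    "ReconstructionWeights",
    "default_basis",
    "fit_weights",
    "reconstruct",
    "select",
]


@dataclass(frozen=True)
class NeighborBasis:
    """Which landmark is reconstructed from which neighbors."""

    center_id: int
    neighbor_ids: tuple[int, ...]

    def __post_init__(self):
        if self.center_id in self.neighbor_ids:
            raise ValueError("center landmark cannot be its own neighbor")
        if len(self.neighbor_ids) < 3:
            raise ValueError("affine reconstruction needs at least 3 neighbors")


@dataclass(frozen=True)
class ReconstructionWeights:
    omega: np.ndarray  # (k,)
    basis: NeighborBasis


def default_basis(side: str) -> NeighborBasis:
    """Per-eye default: the 4 eye-contour + 2 nearest eyebrow landmarks."""
    s = LANDMARK_SCHEME_29
    if side == "left":
        ids = ("left_eye_outer", "left_eye_top", "left_eye_inner", "left_eye_bottom",
               "left_brow_mid", "left_brow_inner")
        center = "left_eye_center"
    elif side == "right":
        ids = ("right_eye_inner", "right_eye_top", "right_eye_outer", "right_eye_bottom",
               "right_brow_inner", "right_brow_mid")
        center = "right_eye_center"
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return NeighborBasis(center_id=s[center], neighbor_ids=tuple(s[i] for i in ids))


def fit_weights(
    training_shapes,
    basis: NeighborBasis,
    constrained: bool = True,
    ridge: float = 1e-8,
) -> ReconstructionWeights:
    """Fit reconstruction weights over a set of training shapes.

    Minimizes sum_shapes ||m_c - M' omega||^2, by default subject to
    sum(omega) = 1 (the affine-invariance constraint), via the KKT
    system of the constrained least-squares problem. A small ridge term
    regularizes rank-deficient neighbor configurations.
    """
    k = len(basis.neighbor_ids)
    if len(training_shapes) < 1:
        raise ValueError("need at least one training shape")
    # Stack per-shape neighbor matrices: rows are (n_shapes * 2) x k.
    rows, rhs = [], []
    for shape in training_shapes:
        shape = np.asarray(shape, dtype=np.float64)
        M = shape[list(basis.neighbor_ids)]  # (k, 2)
        rows.append(M.T)  # x-row and y-row
        rhs.append(shape[basis.center_id])
    A = np.vstack(rows)  # (2n, k)
    b = np.concatenate(rhs)  # (2n,)
    AtA = A.T @ A + ridge * np.eye(k)
    Atb = A.T @ b
    if constrained:
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = AtA
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs_full = np.append(Atb, 1.0)
        omega = np.linalg.solve(kkt, rhs_full)[:k]
    else:
        omega = np.linalg.solve(AtA, Atb)
    return ReconstructionWeights(omega=omega, basis=basis)


def reconstruct(shape: np.ndarray, w: ReconstructionWeights) -> np.ndarray:
    """Reconstructed eye center m' = M' @ omega for one shape."""
    shape = np.asarray(shape, dtype=np.float64)
    ids = list(w.basis.neighbor_ids)
    if max(ids + [w.basis.center_id]) >= len(shape):
        raise ValueError(
            f"shape with {len(shape)} landmarks lacks basis indices {w.basis}"
        )
    return shape[ids].T @ w.omega


def select(candidates: CandidateSet, m_prime: np.ndarray):
    """Pick the candidate nearest the reconstructed center.

    Returns ``(point (x, y), fallback)``. Ties break toward higher vote
    response, then lower scale index. An empty candidate set returns
    the reconstruction itself with ``fallback=True``.
    """
    m_prime = np.asarray(m_prime, dtype=np.float64)
    if len(candidates) == 0:
        return m_prime.copy(), True
    best = min(
        candidates,
        key=lambda c: (np.hypot(c.x - m_prime[0], c.y - m_prime[1]), -c.response, c.scale_index),
    )
    return np.array([best.x, best.y]), False
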