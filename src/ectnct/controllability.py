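"""Average and modal controllability of structural brain networks.

The dynamical substrate is the standard noise-free, discrete-time, linear
time-invariant network model

    x(t+1) = A x(t) + B u(t)

where ``A`` is the structural adjacency matrix normalized to Schur stability
(all eigenvalues strictly inside the unit circle) by dividing by
``c + lambda_max`` with scaling constant ``c = 1``, and ``B = e_i`` selects a
single input region.

Two regional metrics summarize how an input at region *i* can steer this
system:

* **Average controllability** ``ac[i] = trace(W_i)``, the trace of the
  infinite-horizon controllability Gramian
  ``W_i = sum_tau A^tau e_i e_i^T (A^T)^tau``, i.e. the total impulse-response
  energy spread through the network from an input at *i*. Computed by solving
  the discrete Lyapunov equation ``W = A W A^T + Q``.
* **Modal controllability** ``mc[i] = sum_j (1 - lambda_j^2) v_ij^2`` over the
  eigenpairs ``(lambda_j, v_j)`` of symmetric ``A`` — the ability of region
  *i* to steer the fast-decaying (small ``|lambda|``) dynamic modes.

Whole-brain values are the arithmetic means across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .connectome import Connectome

__all__ = [
    "StableSystem",
    "ControllabilityProfile",
    "stabilize",
    "average_controllability",
    "modal_controllability",
    "whole_brain_means",
    "controllability_profile",
]


@dataclass(frozen=True)
class StableSystem:
    """A Schur-stable system matrix derived from a connectome.

    Attributes
    ----------
    A
        N x N system matrix with spectral radius < 1.
    source_lambda_max
        Largest eigenvalue of the raw (pre-normalization) adjacency.
    """

    A: np.ndarray = field(repr=False)
    source_lambda_max: float = float("nan")

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"system matrix must be square, got {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("non-finite entries in system matrix")
        rho = self.spectral_radius if A.size else 0.0
        if rho >= 1.0:
            raise ValueError(f"system is not Schur-stable (spectral radius {rho:.6g})")
        object.__setattr__(self, "A", A)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A)))) if self.A.size else 0.0

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.A, self.A.T, rtol=0.0, atol=1e-9))


@dataclass(frozen=True)
class ControllabilityProfile:
    """Per-node and whole-brain controllability of one subject's network."""

    ac: np.ndarray
    mc: np.ndarray
    ac_mean: float
    mc_mean: float


def stabilize(c: Connectome, scaling_constant: float = 1.0) -> StableSystem:
    """Normalize an adjacency matrix into a Schur-stable system matrix.

    ``A = W / (scaling_constant + lambda_max(W))`` with the conventional unit
    scaling constant, which maps the largest eigenvalue to
    ``lambda_max / (1 + lambda_max) < 1``.
    """
    if scaling_constant <= 0:
        raise ValueError("scaling_constant must be positive")
    w = c.weights
    if w.size == 0:
        raise ValueError("empty matrix")
    lam = linalg.eigvalsh(w)
    lam_max = float(lam[-1])
    if not np.isfinite(lam_max):
        raise ValueError("non-finite eigenvalues")
    A = w / (scaling_constant + lam_max)
    return StableSystem(A=A, source_lambda_max=lam_max)


def average_controllability(s: StableSystem) -> np.ndarray:
    """Per-node average controllability ``ac[i] = trace(W_i)``.

    For symmetric ``A``, ``trace(W_i) = sum_tau ||A^tau e_i||^2`` is the i-th
    diagonal entry of the aggregate Gramian ``W = sum_tau A^tau (A^T)^tau``,
    so a single Lyapunov solve ``W = A W A^T + I`` yields all nodes at once.
    Every entry is >= 1 because the horizon-0 term contributes exactly 1.
    """
    if not s.is_symmetric:
        raise ValueError("average_controllability requires a symmetric system matrix")
    n = s.n_nodes
    # bilinear method: O(n^3), avoids the O(n^4)-memory Kronecker direct solve
    W = linalg.solve_discrete_lyapunov(s.A, np.eye(n), method="bilinear")
    ac = np.diag(W).copy()
    if not np.all(np.isfinite(ac)):
        raise ValueError("Lyapunov solution is not finite (system near-unstable)")
    return ac


def modal_controllability(s: StableSystem) -> np.ndarray:
    """Per-node modal controllability ``mc[i] = sum_j (1 - lambda_j^2) v_ij^2``.

    Requires a symmetric system matrix, which guarantees a real orthonormal
    eigenbasis; asymmetric input is refused rather than silently evaluated in
    a non-orthonormal basis. For stable symmetric ``A`` every entry lies in
    (0, 1].
    """
    if not s.is_symmetric:
        raise ValueError("modal_controllability requires a symmetric system matrix")
    lam, V = np.linalg.eigh(s.A)
    return (V**2) @ (1.0 - lam**2)


def whole_brain_means(ac: np.ndarray, mc: np.ndarray) -> tuple[float, float]:
    """Whole-brain controllability: arithmetic means of the per-node vectors."""
    ac = np.asarray(ac, dtype=float)
    mc = np.asarray(mc, dtype=float)
    if ac.size == 0 or mc.size == 0:
        raise ValueError("empty controllability vector")
    if ac.shape != mc.shape:
        raise ValueError("ac and mc must have the same length")
    return float(ac.mean()), float(mc.mean())


def controllability_profile(s: StableSystem) -> ControllabilityProfile:
    """Compute the full per-node + whole-brain controllability profile."""
    ac = average_controllability(s)
    mc = modal_controllability(s)
    ac_mean, mc_mean = whole_brain_means(ac, mc)
    return ControllabilityProfile(ac=ac, mc=mc, ac_mean=ac_mean, mc_mean=mc_mean)
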