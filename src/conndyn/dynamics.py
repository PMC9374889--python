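"""Per-node controllability of the linear network dynamics.

The dynamics model is the noise-free discrete-time linear time-invariant
system x_{t+1} = Ā x_t + B_K u_K(t) on the stabilized structural matrix Ā,
controlling one node at a time (B_K = e_k). Two per-node statistics are
computed in closed form:

* average controllability — Trace of the infinite-horizon controllability
  Gramian W_k = Σ_τ Ā^τ e_k e_kᵀ (Ā^τ)ᵀ, which for symmetric stable Ā equals
  the k-th diagonal entry of (I − Ā²)^{-1}. Large values mark nodes that can
  push the system to easy-to-reach states with little input energy.
* modal controllability — φ_i = Σ_j (1 − λ_j²) v_ij² over the eigenmodes
  Ā = VΛVᵀ. Large values mark nodes able to steer the system into
  fast-decaying, difficult-to-reach modes.

The closed form is preferred over per-node series sums: it is exact and one
O(N³) solve per subject, and avoids the ill-conditioned inverse-Gramian
route entirely.
"""

from __future__ import annotations

import logging

import numpy as np

from .connectome import StabilizedMatrix

logger = logging.getLogger("conndyn")


class UnstableMatrixError(ValueError):
    """Spectral radius ≥ 1; the Gramian series does not converge."""


def _as_stable_array(S: StabilizedMatrix | np.ndarray) -> np.ndarray:
    A = S.A_bar if isinstance(S, StabilizedMatrix) else np.asarray(S, dtype=float)
    if np.max(np.abs(A - A.T)) > 1e-9:
        raise ValueError("matrix must be symmetric")
    rho = float(np.linalg.norm(A, ord=2)) if A.size else 0.0
    if rho >= 1.0:
        raise UnstableMatrixError("unstable matrix: stabilize first")
    return A


def average_controllability(S: StabilizedMatrix | np.ndarray) -> np.ndarray:
    """Per-node trace of the single-input controllability Gramian.

    Returns the diagonal of (I − Ā²)^{-1}; every entry is ≥ 1 because the
    τ=0 term of the Gramian series contributes exactly 1.
    """
    A = _as_stable_array(S)
    n = A.shape[0]
    vals = np.diag(np.linalg.inv(np.eye(n) - A @ A)).copy()
    return vals


def modal_controllability(S: StabilizedMatrix | np.ndarray) -> np.ndarray:
    """φ_i = Σ_j (1 − λ_j²) v_ij² over the orthonormal eigenmodes of Ā.

    Values lie in (0, 1] for a stabilized symmetric matrix. The quantity is
    basis-stable under eigenvalue degeneracy: the inner sum over an
    orthonormal basis of a degenerate eigenspace is rotation-invariant.
    """
    A = _as_stable_array(S)
    lam, V = np.linalg.eigh(A)
    return (V**2) @ (1.0 - lam**2)


def gramian_spectrum_diagnostic(S: StabilizedMatrix | np.ndarray) -> float:
    """Smallest eigenvalue of the full-control Gramian (B = I), logged.

    Single-node Gramians of sparse graphs are routinely near-singular; this
    diagnostic reports how far the full-control system is from losing
    controllability but does not gate the metric computation.
    """
    A = _as_stable_array(S)
    n = A.shape[0]
    W = np.linalg.inv(np.eye(n) - A @ A)  # Σ_τ Ā^τ I (Ā^τ)ᵀ for symmetric Ā
    smallest = float(np.linalg.eigvalsh(W)[0])
    logger.info("full-control Gramian smallest eigenvalue: %.3e", smallest)
    return smallest


def simulate(
    S: StabilizedMatrix | np.ndarray,
    x0: np.ndarray,
    steps: int,
    control_node: int | None = None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate x_{t+1} = Ā x_t + e_k u(t); returns the (steps+1, N) trajectory.

    Test utility: the metrics themselves are computed in closed form, the
    trajectory simulation exists to exercise the dynamics model directly.
    """
    A = S.A_bar if isinstance(S, StabilizedMatrix) else np.asarray(S, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n = A.shape[0]
    if x0.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},), got {x0.shape}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if (control_node is None) != (u is None):
        raise ValueError("control_node and u must be supplied together")
    if u is not None:
        u = np.asarray(u, dtype=float)
        if u.shape != (steps,):
            raise ValueError(f"u must have shape ({steps},), got {u.shape}")
        if not 0 <= control_node < n:
            raise ValueError("control_node out of range")
    X = np.empty((steps + 1, n))
    X[0] = x0
    for t in range(steps):
        X[t + 1] = A @ X[t]
        if u is not None:
            X[t + 1, control_node] += u[t]
    return X
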