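"""Global and regional synchronizability from the graph Laplacian spectrum.

Synchronizability measures a network's ability to sustain a single
synchronous state. Linear stability of the synchronous state depends on the
positive eigenvalues λ_1..λ_{N−1} of the Laplacian L = D − A; a tight
eigenvalue cluster synchronizes more readily, so the statistic is the
inverse normalized spread

    1/σ² = d̄² (N−1) / Σ_i (λ_i − λ̄)²,

with λ̄ the mean nonzero eigenvalue and d̄ = (1/N) Σ_i Σ_{j≠i} A_ij the mean
coupling strength per node (which makes the measure invariant to uniform
weight rescaling).

The regional split distributes the spread over nodes through the Laplacian
eigenvector loadings: s_i = Σ_{j: λ_j>0} (λ_j − λ̄)² u_ij². This is the
linear decomposition of the spread that sums exactly to the global spread,
is permutation-equivariant, and assigns equal values on vertex-transitive
graphs; regional_i = d̄²(N−1) / (N·s_i), so equal loadings reproduce the
global value. This split is an interpretation choice — see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import Connectome

logger = logging.getLogger("conndyn")

#: eigenvalues below this fraction of the largest are treated as zero
ZERO_EIG_RTOL = 1e-9


class DisconnectedGraphError(ValueError):
    """More than one zero Laplacian eigenvalue: synchronizability undefined."""


@dataclass(frozen=True)
class SynchronizabilityResult:
    """Spectral synchronizability of one connectome.

    ``degenerate`` flags a zero eigenvalue spread (all nonzero eigenvalues
    equal, e.g. a complete graph); the value sentinels are then +inf and are
    excluded from group statistics downstream.
    """

    global_value: float
    regional_values: np.ndarray
    laplacian_eigenvalues: np.ndarray
    mean_nonzero_eigenvalue: float
    d_bar: float
    degenerate: bool = False


def graph_laplacian(c: Connectome | np.ndarray) -> np.ndarray:
    """L = D − A with D = diag(node strengths); symmetric PSD, zero row sums."""
    A = c.A if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    return np.diag(A.sum(axis=1)) - A


def global_synchronizability(c: Connectome | np.ndarray) -> SynchronizabilityResult:
    """Inverse normalized Laplacian eigenvalue spread (higher = more synchronizable)."""
    A = c.A if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    n = A.shape[0]
    L = graph_laplacian(A)
    lam, U = np.linalg.eigh(L)
    tol = ZERO_EIG_RTOL * max(lam[-1], 1.0)
    n_zero = int(np.sum(lam <= tol))
    if n_zero > 1:
        raise DisconnectedGraphError(
            f"disconnected: synchronizability undefined ({n_zero} zero eigenvalues)"
        )
    nonzero = lam[1:]
    lam_bar = float(nonzero.mean())
    spread = float(np.sum((nonzero - lam_bar) ** 2))
    d_bar = float(A.sum() / n)

    # per-node loadings of the spread; columns 1.. are the nonzero modes
    s = (U[:, 1:] ** 2) @ ((nonzero - lam_bar) ** 2)

    if spread <= 1e-12 * max(lam_bar**2, 1.0):
        logger.info("degenerate spectrum (zero eigenvalue spread); flagging infinite")
        return SynchronizabilityResult(
            global_value=np.inf,
            regional_values=np.full(n, np.inf),
            laplacian_eigenvalues=lam,
            mean_nonzero_eigenvalue=lam_bar,
            d_bar=d_bar,
            degenerate=True,
        )

    global_value = d_bar**2 * (n - 1) / spread
    with np.errstate(divide="ignore"):
        regional = np.where(s > 0, d_bar**2 * (n - 1) / (n * s), np.inf)
    n_inf = int(np.sum(~np.isfinite(regional)))
    if n_inf:
        logger.info("%d regions with zero spread loading flagged infinite", n_inf)
    return SynchronizabilityResult(
        global_value=global_value,
        regional_values=regional,
        laplacian_eigenvalues=lam,
        mean_nonzero_eigenvalue=lam_bar,
        d_bar=d_bar,
    )


def regional_synchronizability(c: Connectome | np.ndarray) -> np.ndarray:
    """Per-node synchronizability from the eigenvector-loading split."""
    return global_synchronizability(c).regional_values
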