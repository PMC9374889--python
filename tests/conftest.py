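import numpy as np
import pytest

from conndyn import CohortSpec, generate_cohort
from conndyn.synthetic import module_scale_model


def random_stable_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix with spectral radius < 1 (stabilized form)."""
    A = rng.normal(size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    sigma0 = np.linalg.norm(A, ord=2)
    return A / (1.0 + sigma0)


def random_connectome_matrix(rng: np.random.Generator, n: int, density: float = 0.4) -> np.ndarray:
    """Random nonnegative symmetric integer-weighted zero-diagonal matrix."""
    iu = np.triu_indices(n, k=1)
    w = np.where(rng.random(len(iu[0])) < density, np.rint(rng.lognormal(1.5, 0.6, len(iu[0]))), 0.0)
    A = np.zeros((n, n))
    A[iu] = np.maximum(w, 0.0)
    return A + A.T


@pytest.fixture(scope="session")
def small_cohort():
    """Null three-group cohort, small enough for fast statistics tests."""
    spec = CohortSpec(
        n_regions=20,
        group_sizes=(("HC", 24), ("SZ", 16), ("BD", 16)),
        seed=123,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def sz_signal_cohort():
    """SZ-only cohort whose BDRS scale tracks module 0's controllability profile."""
    base = CohortSpec(n_regions=30, group_sizes=(("SZ", 45),), seed=7)
    spec = CohortSpec(
        n_regions=30,
        group_sizes=(("SZ", 45),),
        scale_models=(module_scale_model("BDRS", "SZ", base),),
        seed=7,
    )
    return generate_cohort(spec)
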