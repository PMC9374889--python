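"""Structural connectome data model and I/O.

A connectome is a weighted undirected graph whose nodes are atlas-defined
brain regions and whose edge weights count white-matter streamlines
reconstructed between region pairs. This module holds the validated
in-memory representation, readers/writers for the plain-text formats used
throughout the package, the region/system metadata table, and the spectral
stabilization step that every controllability computation relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("conndyn")

#: absolute tolerance for A == A.T; streamline counts are integers in
#: principle, so larger drift indicates corrupt input rather than noise.
SYMMETRY_TOL = 1e-9

#: the seven canonical cortical functional systems plus a subcortical level
#: for regions outside the cortical mapping.
YEO_SYSTEMS = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "ventral attention",
    "limbic",
    "frontal-parietal",
    "default mode",
    "subcortical",
)

LOBES = ("frontal", "temporal", "parietal", "occipital", "insular", "limbic", "subcortical")


class ConnectomeError(ValueError):
    """Raised when a matrix violates the connectome invariants."""


@dataclass
class Connectome:
    """One subject's weighted symmetric adjacency matrix.

    Attributes
    ----------
    subject_id : str
        Opaque subject label.
    A : ndarray of shape (N, N)
        Nonnegative symmetric edge weights (streamline counts), zero diagonal.
    region_ids : list of str
        Ordered region labels; internal indexing is 0-based, the labels carry
        the atlas's own (typically 1-based) naming as opaque strings.
    """

    subject_id: str
    A: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ConnectomeError(f"adjacency matrix must be square, got shape {A.shape}")
        n = A.shape[0]
        if n < 2:
            raise ConnectomeError("connectome needs at least 2 regions")
        if not np.all(np.isfinite(A)):
            raise ConnectomeError("non-finite entries in adjacency matrix")
        asym = np.max(np.abs(A - A.T))
        if asym > SYMMETRY_TOL:
            raise ConnectomeError(f"asymmetric matrix: max |A - A.T| = {asym:g}")
        A = (A + A.T) / 2.0
        if np.any(A < 0):
            raise ConnectomeError("negative edge weight")
        if np.any(np.diag(A) != 0):
            raise ConnectomeError("nonzero diagonal (self-loops are not allowed)")
        self.A = A
        if not self.region_ids:
            self.region_ids = [str(i + 1) for i in range(n)]
        if len(self.region_ids) != n:
            raise ConnectomeError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class StabilizedMatrix:
    """Adjacency matrix rescaled so the linear dynamics are stable.

    ``A_bar = A / (1 + sigma0)`` where ``sigma0`` is the largest singular
    value of A; for symmetric A this guarantees spectral radius < 1 so the
    infinite-horizon controllability Gramian series converges.
    """

    A_bar: np.ndarray
    sigma0: float


def stabilize(c: Connectome | np.ndarray) -> StabilizedMatrix:
    """Divide the adjacency matrix by one plus its largest singular value."""
    A = c.A if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if A.size == 0 or not np.any(A):
        return StabilizedMatrix(A_bar=np.zeros_like(A), sigma0=0.0)
    # for symmetric A the largest singular value is the largest |eigenvalue|
    sigma0 = float(np.linalg.norm(A, ord=2))
    return StabilizedMatrix(A_bar=A / (1.0 + sigma0), sigma0=sigma0)


# ---------------------------------------------------------------------------
# file I/O

def read_connectome(
    path: str | Path,
    format: str = "dense",
    subject_id: str | None = None,
    region_ids: Sequence[str] | None = None,
    repair_diagonal: bool = False,
) -> Connectome:
    """Read a connectome from a plain-text file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"dense"`` — whitespace- or comma-separated N×N grid with an
        optional header row of region ids; ``"edges"`` — three columns
        (region_a, region_b, weight), undirected, absent pairs are zero.
    region_ids
        Required for the edge-list format (defines node order); overrides
        any header for the dense format.
    repair_diagonal
        Zero a nonzero diagonal with a warning instead of raising.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    if format == "dense":
        A, header_ids = _read_dense(path)
        ids = list(region_ids) if region_ids is not None else header_ids
    elif format == "edges":
        if region_ids is None:
            raise ValueError("edge-list format requires region_ids")
        ids = list(region_ids)
        index = {r: i for i, r in enumerate(ids)}
        A = np.zeros((len(ids), len(ids)))
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                a, b, w = parts[0], parts[1], float(parts[2])
                i, j = index[a], index[b]
                A[i, j] = w
                A[j, i] = w
    else:
        raise ValueError(f"unknown connectome format {format!r}")

    if repair_diagonal and np.any(np.diag(A) != 0):
        logger.warning("%s: zeroing %d nonzero diagonal entries", path, int(np.count_nonzero(np.diag(A))))
        np.fill_diagonal(A, 0.0)
    return Connectome(subject_id=sid, A=A, region_ids=ids or [])


def _read_dense(path: Path) -> tuple[np.ndarray, list[str] | None]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ConnectomeError(f"{path}: empty file")

    def tokens(line: str) -> list[str]:
        return line.replace(",", " ").split()

    first = tokens(lines[0])
    header: list[str] | None = None
    try:
        [float(t) for t in first]
        # an all-numeric first row can still be a header of numeric region
        # ids: a square matrix has as many rows as columns
        if len(lines) == len(first) + 1:
            header = first
            lines = lines[1:]
    except ValueError:
        header = first
        lines = lines[1:]
    rows = [[float(t) for t in tokens(ln)] for ln in lines]
    A = np.array(rows, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ConnectomeError(f"{path}: parsed matrix is not square (shape {A.shape})")
    return A, header


def write_connectome(c: Connectome, path: str | Path, header: bool = True) -> None:
    """Write the dense-delimited dialect (round-trips with read_connectome)."""
    with open(path, "w") as fh:
        if header:
            fh.write(" ".join(c.region_ids) + "\n")
        for row in c.A:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# region metadata

def read_region_table(path: str | Path) -> pd.DataFrame:
    """Read a region metadata table (region_id, region_name, hemisphere, lobe, yeo_system)."""
    rt = pd.read_csv(path, sep=None, engine="python", dtype={"region_id": str})
    return validate_region_table(rt)


def validate_region_table(rt: pd.DataFrame) -> pd.DataFrame:
    required = {"region_id", "region_name", "hemisphere", "lobe", "yeo_system"}
    missing = required - set(rt.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    if rt["region_id"].duplicated().any():
        raise ValueError("duplicate region_ids in region table")
    bad = set(rt["yeo_system"]) - set(YEO_SYSTEMS)
    if bad:
        raise ValueError(f"unknown yeo_system levels: {sorted(bad)}")
    bad_h = set(rt["hemisphere"]) - {"L", "R"}
    if bad_h:
        raise ValueError(f"hemisphere must be L or R, got {sorted(bad_h)}")
    return rt


def default_region_table(n_regions: int = 246) -> pd.DataFrame:
    """Generate a synthetic atlas-like region table.

    Produces a deterministic table in the style of a 246-region whole-brain
    parcellation: left/right homotopic pairs, lobe labels, and membership in
    the seven cortical functional systems plus a subcortical level. The
    assignment is synthetic — a stand-in layout for tests and simulated
    cohorts, not the real atlas-to-system mapping.
    """
    rows = []
    # roughly 5/6 cortical, 1/6 subcortical, mirroring a cortex+subcortex atlas
    n_subcortical = max(2, n_regions // 6) if n_regions >= 12 else 0
    n_cortical = n_regions - n_subcortical
    cortical_systems = YEO_SYSTEMS[:7]
    cortical_lobes = LOBES[:6]
    for i in range(n_regions):
        region_id = str(i + 1)
        hemi = "L" if i % 2 == 0 else "R"
        if i < n_cortical:
            system = cortical_systems[(i // 2) % len(cortical_systems)]
            lobe = cortical_lobes[(i // 2) % len(cortical_lobes)]
            name = f"ctx_{lobe}_{(i // 2) + 1}_{hemi}"
        else:
            system = "subcortical"
            lobe = "subcortical"
            name = f"subctx_{(i - n_cortical) // 2 + 1}_{hemi}"
        rows.append((region_id, name, hemi, lobe, system))
    return pd.DataFrame(rows, columns=["region_id", "region_name", "hemisphere", "lobe", "yeo_system"])


# ---------------------------------------------------------------------------
# subject manifest

MANIFEST_COLUMNS = ("subject_id", "group", "age", "sex", "connectome_path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a subject manifest (subject_id, group, age, sex, connectome path, scale columns)."""
    m = pd.read_csv(path, sep=None, engine="python", dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(m.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if m["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_ids in manifest")
    return m
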