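"""p-nearest-neighbor graphs, similarity sparsification, and graph Laplacians.

The neighbor graph weights mutual neighbors 1, one-sided neighbors 1/2 and
non-neighbors 0.  Multiplying a similarity matrix elementwise by this weight
matrix yields the sparsified similarity Ŝ from which the (normalized) graph
Laplacian used by the solver is built:

    L = D − Ŝ,   D(i,i) = Σ_r Ŝ(i,r),   L̃ = D^{−1/2} L D^{−1/2}.

For nonnegative Ŝ, L is positive semidefinite and the eigenvalues of L̃ lie
in [0, 2].  Signed similarities (possible for Pearson) are handled literally
— degrees are signed sums — but the spectral guarantees then no longer hold;
the fitting pipeline clips negatives by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix, ValidationError

__all__ = [
    "NeighborGraph",
    "SparsifiedSimilarity",
    "LaplacianPair",
    "build_pnn_graph",
    "sparsify",
    "laplacians",
]


@dataclass
class NeighborGraph:
    """Symmetric weight matrix with entries in {0, 1/2, 1}."""

    N: np.ndarray
    p: int

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if not np.isin(self.N, (0.0, 0.5, 1.0)).all():
            raise ValidationError("neighbor graph entries must be 0, 1/2 or 1")
        if not np.array_equal(self.N, self.N.T):
            raise ValidationError("neighbor graph must be symmetric")


@dataclass
class SparsifiedSimilarity:
    """Elementwise product of a similarity matrix with a neighbor graph."""

    S_hat: np.ndarray
    source_similarity_id: str = "unnamed"

    def __post_init__(self) -> None:
        self.S_hat = np.asarray(self.S_hat, dtype=float)
        if not np.array_equal(self.S_hat, self.S_hat.T):
            raise ValidationError("sparsified similarity must be symmetric")


@dataclass
class LaplacianPair:
    """Unnormalized and normalized graph Laplacian plus the degree vector."""

    L: np.ndarray
    L_tilde: np.ndarray
    D: np.ndarray


def _neighbor_sets(S: np.ndarray, p: int) -> np.ndarray:
    """Boolean membership matrix M with M[i, j] = True iff j ∈ Np(i).

    Np(i) holds the p indices j ≠ i with the largest S(i, j); ties are
    broken toward the smallest index so the construction is deterministic.
    """
    n = S.shape[0]
    M = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (-S[i, j], j))
        M[i, order[:p]] = True
    return M


def build_pnn_graph(S: SimilarityMatrix | np.ndarray, p: int) -> NeighborGraph:
    """Construct the p-nearest-neighbor weight matrix N.

    N(i, j) is 1 when i and j are in each other's p-neighbor sets, 0 when
    neither is in the other's, and 1/2 for one-sided membership.  The
    diagonal is 0 (an entity is not its own neighbor).
    """
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = A.shape[0]
    if not isinstance(p, (int, np.integer)) or isinstance(p, bool):
        raise ValidationError("p must be a positive integer")
    if p < 1:
        raise ValidationError("p must be at least 1")
    if p >= n:
        raise ValidationError(f"p={p} must be smaller than the number of entities {n}")
    M = _neighbor_sets(A, p)
    N = np.where(M & M.T, 1.0, np.where(~M & ~M.T, 0.0, 0.5))
    np.fill_diagonal(N, 0.0)
    return NeighborGraph(N=N, p=int(p))


def sparsify(S: SimilarityMatrix | np.ndarray, N: NeighborGraph) -> SparsifiedSimilarity:
    """Elementwise product Ŝ(i,j) = N(i,j)·S(i,j)."""
    A = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if A.shape != N.N.shape:
        raise ValidationError(
            f"similarity shape {A.shape} does not match graph shape {N.N.shape}"
        )
    name = getattr(S, "kind", "unnamed") if isinstance(S, SimilarityMatrix) else "unnamed"
    return SparsifiedSimilarity(S_hat=N.N * A, source_similarity_id=str(name))


def laplacians(S_hat: SparsifiedSimilarity | np.ndarray) -> LaplacianPair:
    """Degree vector, Laplacian L = D − Ŝ, and normalized L̃ = D^{−1/2}LD^{−1/2}.

    Zero (or negative) degrees get a 0 entry in D^{−1/2}, so isolated nodes
    contribute nothing to the normalized Laplacian.
    """
    A = S_hat.S_hat if isinstance(S_hat, SparsifiedSimilarity) else np.asarray(S_hat, dtype=float)
    if not np.allclose(A, A.T, atol=0):
        raise ValidationError("sparsified similarity must be symmetric")
    d = A.sum(axis=1)
    L = np.diag(d) - A
    with np.errstate(divide="ignore", invalid="ignore"):
        d_isqrt = np.where(d > 0, d, 1.0) ** -0.5
    d_isqrt = np.where(d > 0, d_isqrt, 0.0)
    L_tilde = d_isqrt[:, None] * L * d_isqrt[None, :]
    return LaplacianPair(L=L, L_tilde=L_tilde, D=d)
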