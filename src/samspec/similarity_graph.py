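"""The weighted community graph and its symmetric normalization.

Pairwise event similarity is the heat kernel s_ij = exp(-D_ij^2 / 2 sigma^2)
with D the Euclidean distance.  The similarity between two communities is
the *sum* of s_ij over all member pairs — deliberately not averaged, so
that populous (dense-region) communities carry larger weights, the way
parallel conductances add in an electrical network.  This is how density
information survives the sampling stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import EventMatrix
from .errors import DisconnectedVertexError
from .sampling import Community, SamplingResult

#: target element count of one kernel slab (rows x all events)
_CHUNK_ELEMENTS = 2**24

__all__ = [
    "CommunityGraph",
    "NormalizedGraph",
    "heat_kernel",
    "community_similarity",
    "build_similarity_matrix",
    "normalize_adjacency",
]


@dataclass(frozen=True)
class CommunityGraph:
    """Symmetric m' x m' matrix of summed pairwise similarities.

    The diagonal S_cc sums over all ordered member pairs of c including
    i=j, so S_cc >= |c| and the degree of a community reflects its total
    internal conductance.
    """

    weights: np.ndarray
    sigma: float
    community_sizes: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        object.__setattr__(
            self, "community_sizes", np.asarray(self.community_sizes, dtype=np.intp)
        )
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(W)) or (W < 0).any():
            raise ValueError("weights must be finite and nonnegative")

    @property
    def m_prime(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class NormalizedGraph:
    """D^(-1/2) A D^(-1/2) of a community graph, with the degrees kept."""

    matrix: np.ndarray
    degree: np.ndarray

    @property
    def m_prime(self) -> int:
        return self.matrix.shape[0]


def heat_kernel(distance, sigma: float):
    """exp(-distance^2 / (2 sigma^2)); 1 at distance 0, decreasing."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    distance = np.asarray(distance, dtype=float)
    if (distance < 0).any():
        raise ValueError("distance must be nonnegative")
    out = np.exp(-(distance**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def community_similarity(
    c: Community, c_prime: Community, data: EventMatrix, sigma: float
) -> float:
    """Sum of heat-kernel similarities over all member pairs (i in c, j in c')."""
    A = data.values[c.member_indices]
    B = data.values[c_prime.member_indices]
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return float(np.exp(-d2 / (2.0 * sigma**2)).sum())


def build_similarity_matrix(
    sampling: SamplingResult, data: EventMatrix, sigma: float
) -> CommunityGraph:
    """Aggregate the full n x n heat kernel into the m' x m' community graph.

    Equivalent to calling :func:`community_similarity` for every pair of
    communities (and each community with itself for the diagonal), but
    computed in row blocks of the event kernel with grouped summation so
    the n x n matrix is never materialized.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    X = data.values
    n = X.shape[0]
    m_prime = sampling.m_prime

    # events sorted by community id -> contiguous groups for reduceat
    order = np.argsort(sampling.membership, kind="stable")
    Xs = np.ascontiguousarray(X[order])
    comm_sorted = sampling.membership[order]
    counts = np.bincount(sampling.membership, minlength=m_prime)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

    sq_norms = (Xs**2).sum(axis=1)
    inv_two_sigma2 = 1.0 / (2.0 * sigma**2)
    S_within = np.zeros((m_prime, m_prime))  # ordered pairs inside a row chunk
    S_cross = np.zeros((m_prime, m_prime))  # pairs straddling chunks, mirrored later

    # block rows sized to keep the kernel slab near ~128 MB
    chunk = max(1, int(_CHUNK_ELEMENTS // max(1, n)))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        rows = slice(start, stop)
        row_comms = comm_sorted[rows]
        cuts = np.flatnonzero(np.r_[True, row_comms[1:] != row_comms[:-1]])
        row_ids = row_comms[cuts]

        # all ordered pairs with both events inside this chunk
        kern = _kernel_block(Xs[rows], Xs[rows], sq_norms[rows], sq_norms[rows], inv_two_sigma2)
        block = np.add.reduceat(np.add.reduceat(kern, cuts, axis=0), cuts, axis=1)
        S_within[np.ix_(row_ids, row_ids)] += block

        # unordered pairs against all later events; mirrored after the loop
        if stop < n:
            kern = _kernel_block(
                Xs[rows], Xs[stop:], sq_norms[rows], sq_norms[stop:], inv_two_sigma2
            )
            j0 = int(comm_sorted[stop])
            col_bounds = np.maximum(starts[j0:] - stop, 0)
            per_comm = np.add.reduceat(kern, col_bounds, axis=1)
            S_cross[row_ids[:, None], np.arange(j0, m_prime)[None, :]] += (
                np.add.reduceat(per_comm, cuts, axis=0)
            )

    S = S_within + S_cross + S_cross.T
    S = 0.5 * (S + S.T)  # symmetrize away block-accumulation round-off
    return CommunityGraph(
        weights=S, sigma=float(sigma), community_sizes=counts
    )


def _kernel_block(A, B, sq_a, sq_b, inv_two_sigma2):
    """Heat-kernel block exp(-|a-b|^2 / 2 sigma^2) for two event slabs.

    Arguments below the double-precision underflow threshold are flushed
    to exact zero, which also avoids the slow denormal path in exp.
    """
    d2 = sq_a[:, None] + sq_b[None, :] - 2.0 * (A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    d2 *= -inv_two_sigma2
    underflow = d2 < -700.0
    np.maximum(d2, -700.0, out=d2)
    np.exp(d2, out=d2)
    d2[underflow] = 0.0
    return d2


def normalize_adjacency(graph: CommunityGraph) -> NormalizedGraph:
    """Symmetric normalization A_hat = D^(-1/2) A D^(-1/2).

    D_ii is the row sum of the weight matrix including the diagonal entry.
    The result has spectrum in [-1, 1] with top eigenvalue exactly 1 for a
    connected graph, and is invariant to a positive rescaling of A.
    """
    A = graph.weights
    degree = A.sum(axis=1)
    if (degree <= 0).any():
        bad = int(np.argmin(degree))
        raise DisconnectedVertexError(
            f"community {bad} has zero total similarity (degree 0)"
        )
    inv_sqrt = 1.0 / np.sqrt(degree)
    A_hat = A * np.outer(inv_sqrt, inv_sqrt)
    A_hat = 0.5 * (A_hat + A_hat.T)
    return NormalizedGraph(matrix=A_hat, degree=degree)
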