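"""Spectral clustering of the normalized community graph.

The number of clusters k is estimated from the eigenvalue curve: for a
well-scaled kernel the first few eigenvalues sit on a plateau near 1
(one per loosely-connected block, by the connected-partition theorem for
the normalized adjacency) and then decay almost linearly.  The knee point
— the intersection of an ordinary-least-squares fit to the decaying
segment with the line y = 1 — estimates k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .similarity_graph import NormalizedGraph

__all__ = [
    "SpectralResult",
    "eigendecompose",
    "estimate_num_clusters",
    "spectral_embed",
    "kmeans_cluster",
    "spectral_cluster",
]

#: eigenvalues within this distance of 1 count as the near-one plateau
PLATEAU_TOL = 1e-3
#: last eigenvalue rank included in the knee-point regression window
REGRESSION_WINDOW_END = 50


@dataclass(frozen=True)
class SpectralResult:
    """Eigendecomposition, estimated k, and per-community cluster labels."""

    eigenvalues: np.ndarray  # sorted descending
    eigenvectors: np.ndarray  # columns aligned to eigenvalues
    k: int
    labels: np.ndarray  # cluster id in 1..k per community
    knee_diagnostics: dict = field(default_factory=dict)


def eigendecompose(graph: NormalizedGraph | np.ndarray):
    """Full symmetric eigendecomposition, eigenvalues sorted descending.

    Each eigenvector's sign is fixed so its largest-magnitude entry is
    positive, making the decomposition deterministic.
    """
    A = graph.matrix if isinstance(graph, NormalizedGraph) else np.asarray(graph)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    scale = max(1.0, float(np.abs(A).max()))
    if np.abs(A - A.T).max() > 1e-8 * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    eigenvalues, eigenvectors = scipy.linalg.eigh(A, driver="evd")
    idx = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[idx]
    eigenvectors = eigenvectors[:, idx]
    anchor = np.argmax(np.abs(eigenvectors), axis=0)
    signs = np.sign(eigenvectors[anchor, np.arange(eigenvectors.shape[1])])
    signs[signs == 0] = 1.0
    return eigenvalues, eigenvectors * signs


def estimate_num_clusters(
    eigenvalues: np.ndarray,
    plateau_tol: float = PLATEAU_TOL,
    window_end: int = REGRESSION_WINDOW_END,
) -> tuple[int, dict]:
    """Knee-point estimate of the number of spectral clusters.

    Counts the plateau of eigenvalues >= 1 - plateau_tol, fits an OLS line
    to (rank, eigenvalue) over the post-plateau window (plateau end + 1 up
    to ``window_end``), and intersects it with y = 1.  The rounded
    x-coordinate of the intersection, clipped to
    [max(2, plateau length), window end], is k.  If the fitted slope is
    nonnegative (no decay) k falls back to the plateau length (min 2).

    Returns (k, diagnostics) where diagnostics records the plateau length
    and fitted line for audit.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 eigenvalues")
    plateau = int(np.count_nonzero(lam >= 1.0 - plateau_tol))
    plateau = max(plateau, 1)
    end = min(lam.size, window_end)
    diagnostics: dict = {"plateau": plateau, "window_end": end}

    ranks = np.arange(plateau + 1, end + 1, dtype=float)
    if ranks.size < 2:
        k = max(2, plateau)
        diagnostics.update(slope=None, intercept=None, fallback="window_too_small")
        return min(k, lam.size), diagnostics

    y = lam[plateau:end]
    slope, intercept = np.polyfit(ranks, y, 1)
    diagnostics.update(slope=float(slope), intercept=float(intercept))
    if slope >= -1e-12:  # flat or rising curve: no knee to intersect
        k = max(2, plateau)
        diagnostics["fallback"] = "nonnegative_slope"
        return min(k, lam.size), diagnostics

    x_cross = (1.0 - intercept) / slope
    k = int(round(x_cross))
    k = int(np.clip(k, max(2, plateau), end))
    diagnostics["knee_x"] = float(x_cross)
    return k, diagnostics


def spectral_embed(eigenvectors: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvector columns with each row scaled to unit norm.

    Rows that are exactly zero are left as zero.
    """
    if k < 1 or k > eigenvectors.shape[1]:
        raise ValueError(f"k={k} out of range for {eigenvectors.shape[1]} vectors")
    U = np.array(eigenvectors[:, :k], dtype=float)
    norms = np.linalg.norm(U, axis=1)
    nonzero = norms > 0
    U[nonzero] /= norms[nonzero, None]
    return U


def kmeans_cluster(
    embedding: np.ndarray, k: int, seed: int = 0, restarts: int = 10
) -> np.ndarray:
    """k-means (k-means++ seeding, best of ``restarts`` runs) on embedding rows.

    Returns 0-based labels.  If the embedding has fewer distinct rows than
    k, k is reduced to the number of distinct rows with a warning.
    """
    embedding = np.asarray(embedding, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(embedding, axis=0).shape[0]
    if k > n_distinct:
        warnings.warn(
            f"k={k} exceeds {n_distinct} distinct embedding rows; reducing k",
            stacklevel=2,
        )
        k = n_distinct
    if k == 1:
        return np.zeros(embedding.shape[0], dtype=np.intp)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        random_state=int(seed) % (2**31),
    )
    return km.fit_predict(embedding).astype(np.intp)


def spectral_cluster(
    graph: NormalizedGraph,
    k_override: int | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> SpectralResult:
    """Eigendecompose, choose k (knee point unless overridden), embed, cluster."""
    eigenvalues, eigenvectors = eigendecompose(graph)
    m_prime = eigenvalues.size
    diagnostics: dict = {}
    if k_override is not None:
        k = int(k_override)
        if not 1 <= k <= m_prime:
            raise ValueError(f"k_override={k} out of range [1, {m_prime}]")
        diagnostics["k_source"] = "override"
    elif m_prime < 3:
        k = m_prime
        diagnostics["k_source"] = "tiny_graph"
    else:
        k, diagnostics = estimate_num_clusters(eigenvalues)
        diagnostics["k_source"] = "knee"
    embedding = spectral_embed(eigenvectors, k)
    labels0 = kmeans_cluster(embedding, k, seed=seed, restarts=restarts)
    return SpectralResult(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        k=int(labels0.max()) + 1,
        labels=labels0 + 1,
        knee_diagnostics=diagnostics,
    )
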