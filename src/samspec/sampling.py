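"""Faithful (density-preserving) sampling of events into communities.

The sampler repeatedly picks a random unregistered event, makes it the
representative of a new community, and registers every still-unregistered
event within Manhattan (L1) distance h of it.  Community sizes therefore
record the local density that the representative set alone would discard.
An outer loop adjusts h so that the number of communities m' lands in
[m/2, m]: with side-2h boxes tiling the occupied volume V, m' scales as
h^(-d), so h is initialized at (V/m)^(1/d)/2 and multiplied by
(m'/m)^(1/d) after each attempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import EventMatrix
from .errors import DegenerateDataError, SamplingNonConvergenceError

__all__ = [
    "Community",
    "SamplingResult",
    "initial_h",
    "faithful_sample",
    "adaptive_sampling",
    "uniform_sample",
    "nearest_representative_labels",
]

#: relative floor substituted for a zero per-dimension range in the
#: bounding-box volume, as a fraction of the largest range
_ZERO_RANGE_FRACTION = 1e-12


@dataclass(frozen=True)
class Community:
    """One representative event plus all events registered to it."""

    representative_index: int
    member_indices: np.ndarray

    def __post_init__(self):
        members = np.asarray(self.member_indices, dtype=np.intp)
        object.__setattr__(self, "member_indices", members)
        if members.size < 1:
            raise ValueError("community must have at least one member")
        if self.representative_index not in members:
            raise ValueError("representative must be a member of its community")

    @property
    def size(self) -> int:
        return int(self.member_indices.size)


@dataclass(frozen=True)
class SamplingResult:
    """Outcome of the adaptive sampling loop.

    membership maps each event index to the index of its community in
    ``communities``.  singleton_fallback marks the degenerate small-input
    path where every event became its own community because n < m/2 makes
    the loop's target range unreachable.
    """

    communities: list[Community]
    h_final: float
    iterations: int
    membership: np.ndarray
    h_trace: list[float] = field(default_factory=list)
    singleton_fallback: bool = False

    @property
    def m_prime(self) -> int:
        return len(self.communities)

    @property
    def representatives(self) -> np.ndarray:
        return np.array(
            [c.representative_index for c in self.communities], dtype=np.intp
        )

    @property
    def community_sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.communities], dtype=np.intp)


def initial_h(data: EventMatrix, m: int) -> float:
    """Initial neighbourhood radius h0 = (V/m)^(1/d) / 2.

    V is the volume of the axis-aligned bounding box of the data; a zero
    range in any dimension is replaced by a small fraction of the largest
    range so a flat dimension does not annihilate the volume.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    X = data.values
    ranges = X.max(axis=0) - X.min(axis=0)
    largest = float(ranges.max())
    if largest <= 0.0:
        raise DegenerateDataError("all events identical: bounding box has no extent")
    ranges = np.where(ranges > 0, ranges, _ZERO_RANGE_FRACTION * largest)
    volume = float(np.prod(ranges))
    return 0.5 * (volume / m) ** (1.0 / data.d)


def faithful_sample(
    data: EventMatrix, h: float, pick_order: np.ndarray
) -> list[Community]:
    """Partition all events into communities at neighbourhood radius h.

    Follows pick_order (a permutation of 0..n-1), skipping events already
    registered to an earlier community.  Membership uses the L1 metric.

    In low dimension a uniform cell grid of side h restricts each
    neighbourhood scan to adjacent cells; the result is identical to the
    plain linear scan, which remains the fallback for d > 6 where the
    3^d-cell neighbourhood would outgrow the point count.
    """
    if not h > 0:
        raise ValueError("h must be positive")
    X = data.values
    n = X.shape[0]
    pick_order = np.asarray(pick_order, dtype=np.intp)
    if pick_order.shape != (n,) or not np.array_equal(
        np.sort(pick_order), np.arange(n)
    ):
        raise ValueError("pick_order must be a permutation of 0..n-1")
    if data.d <= 6 and n > 256:
        return _faithful_sample_grid(X, h, pick_order)
    return _faithful_sample_scan(X, h, pick_order)


def _faithful_sample_scan(X: np.ndarray, h: float, pick_order: np.ndarray):
    """Reference implementation: linear scan over the unregistered pool."""
    n = X.shape[0]
    registered = np.zeros(n, dtype=bool)
    pool = np.arange(n)
    communities: list[Community] = []
    for p in pick_order:
        if registered[p]:
            continue
        if registered[pool].any():
            pool = pool[~registered[pool]]
        dist = np.abs(X[pool] - X[p]).sum(axis=1)
        members = pool[dist <= h]
        registered[members] = True
        communities.append(Community(int(p), members))
    return communities


def _faithful_sample_grid(X: np.ndarray, h: float, pick_order: np.ndarray):
    """Cell-grid scan: an L1 ball of radius h fits in the 3^d adjacent cells."""
    n, d = X.shape
    cell_coords = np.floor(X / h).astype(np.int64)
    cells: dict[tuple, np.ndarray] = {}
    order = np.lexsort(cell_coords.T[::-1])
    sorted_cells = cell_coords[order]
    boundaries = np.flatnonzero(
        np.r_[True, (sorted_cells[1:] != sorted_cells[:-1]).any(axis=1)]
    )
    for b, e in zip(boundaries, np.r_[boundaries[1:], n]):
        cells[tuple(sorted_cells[b])] = order[b:e]

    offsets = np.stack(
        np.meshgrid(*([np.array([-1, 0, 1])] * d), indexing="ij"), axis=-1
    ).reshape(-1, d)
    registered = np.zeros(n, dtype=bool)
    communities: list[Community] = []
    for p in pick_order:
        if registered[p]:
            continue
        base = cell_coords[p]
        candidates = []
        for off in offsets:
            key = tuple(base + off)
            arr = cells.get(key)
            if arr is None:
                continue
            arr = arr[~registered[arr]]
            cells[key] = arr  # prune registered points for future scans
            if arr.size:
                candidates.append(arr)
        cand = np.concatenate(candidates)
        dist = np.abs(X[cand] - X[p]).sum(axis=1)
        members = np.sort(cand[dist <= h])
        registered[members] = True
        communities.append(Community(int(p), members))
    return communities


def _membership_from(communities: list[Community], n: int) -> np.ndarray:
    membership = np.full(n, -1, dtype=np.intp)
    for ci, comm in enumerate(communities):
        membership[comm.member_indices] = ci
    if (membership < 0).any():
        raise AssertionError("sampling did not register every event")
    return membership


def adaptive_sampling(
    data: EventMatrix,
    m: int,
    seed: int | np.random.Generator = 0,
    max_iterations: int = 20,
) -> SamplingResult:
    """Run faithful sampling, adjusting h until m/2 <= m' <= m.

    Each attempt uses a fresh random pick order.  After an attempt that
    produced m' communities outside the target range, h is updated to
    h * (m'/m)^(1/d) and the sampling repeats.  If n < m/2 the target is
    unreachable by pigeonhole; every event then becomes its own singleton
    community and the result is flagged (singleton_fallback).
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = data.n
    if n > 1 and np.all(data.values == data.values[0]):
        # all events identical: one community holds everything at any h
        return SamplingResult(
            communities=[Community(0, np.arange(n))],
            h_final=0.0,
            iterations=0,
            membership=np.zeros(n, dtype=np.intp),
            h_trace=[],
            singleton_fallback=True,
        )
    if n < m / 2 or n == 1:
        communities = [Community(i, np.array([i])) for i in range(n)]
        return SamplingResult(
            communities=communities,
            h_final=0.0,
            iterations=0,
            membership=np.arange(n, dtype=np.intp),
            h_trace=[],
            singleton_fallback=True,
        )

    h = initial_h(data, m)
    h_trace: list[float] = []
    d = data.d
    for iteration in range(1, max_iterations + 1):
        h_trace.append(h)
        pick_order = rng.permutation(n)
        communities = faithful_sample(data, h, pick_order)
        m_prime = len(communities)
        if m / 2 <= m_prime <= m:
            return SamplingResult(
                communities=communities,
                h_final=h,
                iterations=iteration,
                membership=_membership_from(communities, n),
                h_trace=h_trace,
            )
        h = h * (m_prime / m) ** (1.0 / d)
    raise SamplingNonConvergenceError(
        f"community count did not reach [{m / 2:.0f}, {m}] "
        f"in {max_iterations} iterations",
        h_trace,
    )


def uniform_sample(
    data: EventMatrix, count: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Simple random sample of event indices without replacement.

    The baseline sampler that faithful sampling is designed to replace:
    it selects representatives proportionally to density and can miss
    low-density populations entirely.
    """
    if not 1 <= count <= data.n:
        raise ValueError(f"count must be in [1, {data.n}], got {count}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return np.sort(rng.choice(data.n, size=count, replace=False))


def nearest_representative_labels(
    data: EventMatrix, representatives: np.ndarray, rep_labels: np.ndarray
) -> np.ndarray:
    """Extend labels from representatives to all events by nearest neighbour.

    Each event takes the label of its Euclidean-nearest representative;
    ties go to the representative appearing earliest in the list.
    """
    representatives = np.asarray(representatives, dtype=np.intp)
    rep_labels = np.asarray(rep_labels)
    if representatives.size == 0:
        raise ValueError("representatives must be nonempty")
    if rep_labels.shape != representatives.shape:
        raise ValueError("rep_labels must align with representatives")
    X = data.values
    R = X[representatives]
    out = np.empty(data.n, dtype=rep_labels.dtype)
    chunk = max(1, int(2**22 // max(1, R.shape[0])))
    for start in range(0, data.n, chunk):
        block = X[start : start + chunk]
        d2 = ((block[:, None, :] - R[None, :, :]) ** 2).sum(axis=2)
        out[start : start + chunk] = rep_labels[np.argmin(d2, axis=1)]
    return out
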