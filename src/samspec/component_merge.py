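"""Merging spectral clusters into connected components.

Cell populations typically peak in density at their centre, so the
largest edge weights of a spectral cluster sit at the population core.
If the strongest edge *between* two clusters is comparable to the
strongest edge *within* one of them (ratio above the separation factor),
the two clusters are judged to be fragments of one population and merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .similarity_graph import CommunityGraph

__all__ = [
    "ComponentLabeling",
    "within_similarity",
    "between_similarity",
    "combine_components",
    "extend_labels",
]


@dataclass(frozen=True)
class ComponentLabeling:
    """Final component ids (contiguous from 1) per community, with merge log."""

    component_per_community: np.ndarray
    merge_log: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return int(self.component_per_community.max())


def _weights(S: CommunityGraph | np.ndarray) -> np.ndarray:
    return S.weights if isinstance(S, CommunityGraph) else np.asarray(S)


def within_similarity(component, S) -> float:
    """Maximum internal edge weight of a component (a set of communities).

    A singleton component has no internal edges; its diagonal
    self-similarity stands in so the merge ratio stays defined.
    """
    W = _weights(S)
    idx = np.asarray(sorted(component), dtype=np.intp)
    if idx.size == 0:
        raise ValueError("component must be nonempty")
    if idx.size == 1:
        return float(W[idx[0], idx[0]])
    sub = W[np.ix_(idx, idx)]
    off = sub[~np.eye(idx.size, dtype=bool)]
    return float(off.max())


def between_similarity(component_i, component_j, S) -> float:
    """Maximum edge weight between two disjoint components."""
    W = _weights(S)
    a = np.asarray(sorted(component_i), dtype=np.intp)
    b = np.asarray(sorted(component_j), dtype=np.intp)
    if a.size == 0 or b.size == 0:
        raise ValueError("components must be nonempty")
    if np.intersect1d(a, b).size:
        raise ValueError("components must be disjoint")
    return float(W[np.ix_(a, b)].max())


def combine_components(
    spectral_labels: np.ndarray, S, separation_factor: float
) -> ComponentLabeling:
    """Iteratively merge cluster pairs whose between/within ratio is high.

    Components start as the spectral clusters.  Each round computes
    ratio(i, j) = between(C_i, C_j) / within(C_i) for every ordered pair;
    while some ratio exceeds the separation factor, the pair attaining the
    global maximum (ties to the lexicographically smallest pair) is merged
    and all ratios are recomputed.  A zero within-similarity makes the
    ratio +inf, forcing that merge.  Stops when no ratio exceeds the
    factor or a single component remains.
    """
    if not separation_factor > 0:
        raise ValueError("separation_factor must be positive")
    spectral_labels = np.asarray(spectral_labels)
    uniq = np.unique(spectral_labels)
    components: list[set[int]] = [
        set(np.flatnonzero(spectral_labels == lab)) for lab in uniq
    ]
    merge_log: list[tuple[int, int, float]] = []

    while len(components) > 1:
        within = [within_similarity(c, S) for c in components]
        best: tuple[int, int] | None = None
        best_ratio = -math.inf
        for i in range(len(components)):
            for j in range(len(components)):
                if i == j:
                    continue
                bet = between_similarity(components[i], components[j], S)
                ratio = bet / within[i] if within[i] > 0 else math.inf
                if ratio > best_ratio:
                    best_ratio = ratio
                    best = (i, j)
        if best is None or best_ratio <= separation_factor:
            break
        i, j = min(best[0], best[1]), max(best[0], best[1])
        merge_log.append((i, j, float(best_ratio)))
        components[i] = components[i] | components[j]
        del components[j]

    n_comm = spectral_labels.size
    component_per_community = np.zeros(n_comm, dtype=np.intp)
    # number components by their smallest community index, for determinism
    order = np.argsort([min(c) for c in components])
    for new_id, ci in enumerate(order, start=1):
        component_per_community[sorted(components[ci])] = new_id
    return ComponentLabeling(
        component_per_community=component_per_community, merge_log=merge_log
    )


def extend_labels(
    component_per_community: np.ndarray, membership: np.ndarray
) -> np.ndarray:
    """Label every event with the component id of its community."""
    component_per_community = np.asarray(component_per_community)
    membership = np.asarray(membership, dtype=np.intp)
    return component_per_community[membership]
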