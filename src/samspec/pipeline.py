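"""End-to-end pipeline: sample, weigh, cluster, merge, extend."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .component_merge import combine_components, extend_labels
from .data_io import EventMatrix, RunConfig
from .sampling import adaptive_sampling
from .similarity_graph import build_similarity_matrix, normalize_adjacency
from .spectral_core import spectral_cluster

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    """Final per-event component labels plus stage diagnostics."""

    labels: np.ndarray  # component id in 1..C per event
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


def run_pipeline(config: RunConfig, data: EventMatrix) -> PipelineResult:
    """Run the full clustering pipeline on an event matrix.

    Deterministic given ``config.seed``: sampling pick orders and k-means
    initialization both derive from it.
    """
    root = np.random.SeedSequence(config.seed)
    sampling_seed, kmeans_seed = root.spawn(2)
    rng = np.random.default_rng(sampling_seed)

    sampling = adaptive_sampling(
        data, config.m, seed=rng, max_iterations=config.max_sampling_iterations
    )
    graph = build_similarity_matrix(sampling, data, config.sigma)
    normalized = normalize_adjacency(graph)

    if normalized.m_prime == 1:
        labels = np.ones(data.n, dtype=np.intp)
        diagnostics = _diagnostics(sampling, None, None, [])
        return PipelineResult(labels=labels, diagnostics=diagnostics)

    spectral = spectral_cluster(
        normalized,
        k_override=config.k_override,
        seed=int(kmeans_seed.generate_state(1)[0] % (2**31)),
        restarts=config.kmeans_restarts,
    )
    labeling = combine_components(spectral.labels, graph, config.separation_factor)
    labels = extend_labels(labeling.component_per_community, sampling.membership)
    diagnostics = _diagnostics(sampling, spectral, labeling, labels)
    return PipelineResult(labels=np.asarray(labels, dtype=np.intp), diagnostics=diagnostics)


def _diagnostics(sampling, spectral, labeling, labels) -> dict:
    diag = {
        "m_prime": sampling.m_prime,
        "h_final": sampling.h_final,
        "h_trace": list(sampling.h_trace),
        "sampling_iterations": sampling.iterations,
        "singleton_fallback": sampling.singleton_fallback,
    }
    if spectral is not None:
        diag.update(
            {
                "eigenvalues": spectral.eigenvalues.tolist(),
                "k": spectral.k,
                "knee": spectral.knee_diagnostics,
            }
        )
    else:
        diag.update({"eigenvalues": [1.0], "k": 1, "knee": {}})
    if labeling is not None:
        labels = np.asarray(labels)
        sizes = np.bincount(labels)[1:].tolist()
        diag.update(
            {
                "n_components": labeling.n_components,
                "component_sizes": sizes,
                "merge_log": [
                    {"pair": [int(i), int(j)], "ratio": r}
                    for i, j, r in labeling.merge_log
                ],
            }
        )
    else:
        diag.update({"n_components": 1, "component_sizes": [], "merge_log": []})
    return diag
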