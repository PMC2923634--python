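"""Synthetic benchmarks with ground truth.

The flagship benchmark is a two-dimensional mixture of one dense central
Gaussian (30,000 points, covariance diag(2, 2)) surrounded by four small
sparse anisotropic Gaussians (300 points each) plus 4,000 uniform noise
points — a configuration where uniform subsampling starves the small
populations but density-preserving sampling keeps them representable.
A parameterized 3-D rare-population mixture emulates a triple-positive
rare cell subset (0.1%-2% of events) offset from several major
populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import EventMatrix

__all__ = [
    "MixtureSpec",
    "LabeledEvents",
    "generate_mixture",
    "appendix2_spec",
    "rare_population_spec",
]

#: factor by which the realized cluster bounding box is expanded on each
#: side before uniform noise is drawn over it
NOISE_BOX_EXPANSION = 0.10

#: distance of each small satellite cluster from the central mean, along
#: the +x, +y, -x, -y axes respectively
SATELLITE_DISTANCE = 6.0

#: diagonal covariances of the four satellite clusters
SATELLITE_COVARIANCES = (
    (0.08, 0.30),
    (0.07, 0.08),
    (0.50, 0.10),
    (0.10, 0.70),
)


@dataclass(frozen=True)
class MixtureSpec:
    """A Gaussian mixture plus uniform background noise.

    clusters — list of (mean, covariance, count) triples.
    noise — (box, count): box is ((lo...), (hi...)) or None, meaning
        "the realized cluster bounding box expanded by 10% per side".
    """

    clusters: list[tuple[np.ndarray, np.ndarray, int]]
    noise: tuple[tuple | None, int]
    seed: int = 0

    def __post_init__(self):
        clusters = []
        for mean, cov, count in self.clusters:
            mean = np.asarray(mean, dtype=float)
            cov = np.asarray(cov, dtype=float)
            if int(count) < 0:
                raise ValueError("cluster counts must be nonnegative")
            if cov.shape != (mean.size, mean.size):
                raise ValueError("covariance shape must match mean dimension")
            if np.abs(cov - cov.T).max() > 1e-12 * max(1.0, np.abs(cov).max()):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10 * max(1.0, np.abs(cov).max()):
                raise ValueError("covariance must be positive semi-definite")
            clusters.append((mean, cov, int(count)))
        object.__setattr__(self, "clusters", clusters)

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.clusters) + int(self.noise[1])


@dataclass(frozen=True)
class LabeledEvents:
    """Events plus ground truth: 0 = noise, 1..K = generating cluster."""

    events: EventMatrix
    truth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        truth = np.asarray(self.truth, dtype=np.intp)
        object.__setattr__(self, "truth", truth)
        if truth.size != self.events.n:
            raise ValueError("truth length must equal the number of events")


def generate_mixture(spec: MixtureSpec) -> LabeledEvents:
    """Sample a :class:`MixtureSpec` deterministically from its seed.

    Each cluster's realized count equals its spec count exactly (sampling
    is per cluster, not multinomial).  Noise is drawn last, uniformly over
    the noise box.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for k, (mean, cov, count) in enumerate(spec.clusters, start=1):
        pts = rng.multivariate_normal(mean, cov, size=count, method="svd")
        blocks.append(pts)
        labels.append(np.full(count, k, dtype=np.intp))

    box, noise_count = spec.noise
    noise_count = int(noise_count)
    if noise_count > 0:
        if box is None:
            if not blocks:
                raise ValueError("noise box cannot be derived without clusters")
            pts = np.vstack(blocks)
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            span = hi - lo
            lo = lo - NOISE_BOX_EXPANSION * span
            hi = hi + NOISE_BOX_EXPANSION * span
        else:
            lo = np.asarray(box[0], dtype=float)
            hi = np.asarray(box[1], dtype=float)
        noise = rng.uniform(lo, hi, size=(noise_count, lo.size))
        blocks.append(noise)
        labels.append(np.zeros(noise_count, dtype=np.intp))

    values = np.vstack(blocks)
    truth = np.concatenate(labels)
    d = values.shape[1]
    names = ["x", "y", "z"][:d] if d <= 3 else [f"ch{i+1}" for i in range(d)]
    return LabeledEvents(events=EventMatrix(values, names), truth=truth)


def appendix2_spec(seed: int = 0) -> MixtureSpec:
    """The five-cluster benchmark: dense core, four sparse satellites, noise.

    Central cluster: 30,000 points from N((0,0), diag(2, 2)).  Four
    satellites of 300 points each sit at distance 6 from the centre along
    the +x/+y/-x/-y axes with covariances diag(0.08, 0.30),
    diag(0.07, 0.08), diag(0.50, 0.10) and diag(0.10, 0.70).  4,000 noise
    points are uniform over the realized bounding box expanded by 10%.
    Total n = 35,200.
    """
    directions = [(1, 0), (0, 1), (-1, 0), (0, -1)]
    clusters = [(np.zeros(2), np.diag([2.0, 2.0]), 30_000)]
    for (dx, dy), cov in zip(directions, SATELLITE_COVARIANCES):
        mean = SATELLITE_DISTANCE * np.array([dx, dy], dtype=float)
        clusters.append((mean, np.diag(cov), 300))
    return MixtureSpec(clusters=clusters, noise=(None, 4_000), seed=seed)


def rare_population_spec(
    total: int, rare_fraction: float, seed: int = 0
) -> MixtureSpec:
    """A 3-D mixture with three major populations and one rare offset cluster.

    The rare cluster holds ceil(rare_fraction * total) points, positioned
    high in all three channels like a triple-positive subset; the
    remaining events are split evenly over three major Gaussians.
    rare_fraction must lie in [0.001, 0.02] and yield at least 5 points.
    """
    if not 0.001 <= rare_fraction <= 0.02:
        raise ValueError("rare_fraction must be in [0.001, 0.02]")
    rare_count = math.ceil(rare_fraction * total)
    if rare_count < 5:
        raise ValueError("rare_fraction * total must be at least 5")
    rest = total - rare_count
    base, extra = divmod(rest, 3)
    major_counts = [base + (1 if i < extra else 0) for i in range(3)]
    majors = [
        (np.array([2.0, 2.0, 2.0]), np.diag([2.0, 2.0, 2.0]), major_counts[0]),
        (np.array([10.0, 2.0, 2.0]), np.diag([1.5, 1.5, 1.5]), major_counts[1]),
        (np.array([2.0, 10.0, 2.0]), np.diag([1.5, 1.5, 1.5]), major_counts[2]),
    ]
    rare = (np.array([12.0, 12.0, 12.0]), np.diag([0.2, 0.2, 0.2]), rare_count)
    return MixtureSpec(clusters=majors + [rare], noise=(None, 0), seed=seed)
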