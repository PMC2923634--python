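"""External clustering agreement and rare-population accuracy measures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "f_measure",
    "sensitivity_specificity",
    "match_rare_component",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two labelings of the same events."""

    counts: np.ndarray  # reference classes x result classes
    reference_labels: np.ndarray
    result_labels: np.ndarray

    @property
    def reference_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def result_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def contingency_table(reference, result) -> ContingencyTable:
    reference = np.asarray(reference)
    result = np.asarray(result)
    if reference.shape != result.shape or reference.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    ref_labels, ref_idx = np.unique(reference, return_inverse=True)
    res_labels, res_idx = np.unique(result, return_inverse=True)
    counts = np.zeros((ref_labels.size, res_labels.size), dtype=np.intp)
    np.add.at(counts, (ref_idx, res_idx), 1)
    return ContingencyTable(counts, ref_labels, res_labels)


def f_measure(reference_labels, result_labels) -> float:
    """Reference-size-weighted best-match F1 between two labelings.

    For each reference class i, the best-matching result class j maximizes
    F1_ij = 2 P_ij R_ij / (P_ij + R_ij) with precision P_ij = n_ij / |j|
    and recall R_ij = n_ij / |i|; the score is the |i|/n-weighted sum of
    these maxima.  Equals 1 exactly when the labelings are identical up to
    renaming.  Not symmetric: the first argument is the reference.
    """
    table = contingency_table(reference_labels, result_labels)
    counts = table.counts.astype(float)
    n = counts.sum()
    ref_sizes = counts.sum(axis=1)
    res_sizes = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = counts / res_sizes[None, :]
        recall = counts / ref_sizes[:, None]
        f1 = 2.0 * precision * recall / (precision + recall)
    f1 = np.nan_to_num(f1)
    return float((ref_sizes / n * f1.max(axis=1)).sum())


def sensitivity_specificity(
    result_labels,
    truth_labels,
    positive_truth_label,
    matched_result_label,
) -> tuple[float, float]:
    """Sensitivity and specificity of one called component vs. one truth class.

    Events whose result label equals ``matched_result_label`` are the
    called positives; events whose truth label equals
    ``positive_truth_label`` are the true positives.  Sensitivity is
    TP / (TP + FN); specificity is TN / (TN + FP).
    """
    result_labels = np.asarray(result_labels)
    truth_labels = np.asarray(truth_labels)
    if result_labels.shape != truth_labels.shape:
        raise ValueError("label vectors must align")
    positive = truth_labels == positive_truth_label
    called = result_labels == matched_result_label
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError("positive class is empty")
    tp = int((positive & called).sum())
    tn = int((~positive & ~called).sum())
    fp = int((~positive & called).sum())
    sensitivity = tp / n_pos
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    return sensitivity, specificity


def match_rare_component(result_labels, truth_labels, positive_truth_label):
    """Result label holding the most positive-class events (ties: smaller id)."""
    result_labels = np.asarray(result_labels)
    truth_labels = np.asarray(truth_labels)
    if result_labels.size == 0:
        raise ValueError("empty labelings")
    positive = truth_labels == positive_truth_label
    labels, counts = np.unique(result_labels[positive], return_counts=True)
    if labels.size == 0:
        labels, counts = np.unique(result_labels, return_counts=True)
        return labels.min()
    return labels[np.argmax(counts)]
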