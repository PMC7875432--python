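"""Clustering accuracy against ground truth and improvement metrics.

Accuracy A is the percentage of spikes on the diagonal of the matched
confusion matrix. When the estimated cluster count m exceeds the
ground-truth count q, only the q dominant (largest) estimated clusters
enter the matrix; when m < q the matrix is zero-padded. The estimated-to-
truth correspondence is the one-to-one assignment maximizing the diagonal
sum (Hungarian method) — any fixed ordering would understate A arbitrarily.
Noise spikes (-1) never count as accurate but remain in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "accuracy",
    "time_saved",
    "accuracy_improvement",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """q x q matched confusion matrix (rows = matched estimated clusters)."""

    counts: np.ndarray
    q: int
    m_est: int  # estimated cluster count before dominance/padding

    @property
    def diagonal_sum(self) -> int:
        return int(np.trace(self.counts))


@dataclass
class EvalReport:
    """Comparison of proposed vs conventional sorting on one feature set."""

    accuracy_pct: float | None          # proposed-mechanism accuracy
    accuracy_conventional_pct: float | None
    C_t: float                          # conventional clustering time, seconds
    P_t: float                          # proposed clustering time, seconds
    T_s_pct: float                      # time saved, (C_t - P_t)/C_t * 100
    accuracy_improvement_pp: float | None
    O_L: int
    backend: str
    seed: int
    n_spikes: int = 0
    repeats: int = 1
    confusion: list = field(default_factory=list)  # row-major list of rows


def _dominant_clusters(est: np.ndarray, q: int) -> list[int]:
    """The q largest estimated clusters; ties go to the smaller first-row index."""
    ids = [int(v) for v in np.unique(est) if v != -1]
    sizes = {i: int(np.sum(est == i)) for i in ids}
    first = {i: int(np.argmax(est == i)) for i in ids}
    ids.sort(key=lambda i: (-sizes[i], first[i]))
    return ids[:q]


def confusion_matrix(est_labels, gt_labels) -> ConfusionMatrix:
    """Matched q x q confusion matrix of estimated vs ground-truth clusters.

    Estimated noise (-1) rows are ignored when building the contingency
    table. Rows are permuted by the trace-maximizing assignment.
    """
    est = np.asarray(est_labels, dtype=int)
    gt = np.asarray(gt_labels, dtype=int)
    if est.shape != gt.shape or est.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    if np.any(gt < 0):
        raise ValueError("ground-truth labels must be non-negative")
    gt_ids = np.unique(gt)
    q = len(gt_ids)
    gt_pos = {g: j for j, g in enumerate(gt_ids)}
    est_ids = [int(v) for v in np.unique(est) if v != -1]
    m_est = len(est_ids)
    keep = _dominant_clusters(est, q)
    # contingency of kept estimated clusters x ground-truth clusters, zero-padded to q rows
    counts = np.zeros((q, q), dtype=int)
    for r, e in enumerate(keep):
        rows = est == e
        for g in np.unique(gt[rows]):
            counts[r, gt_pos[g]] = int(np.sum(rows & (gt == g)))
    row_ind, col_ind = linear_sum_assignment(-counts)
    matched = np.zeros_like(counts)
    for r, c in zip(row_ind, col_ind):
        matched[c] = counts[r]  # row r serves ground-truth column c -> place on diagonal
    return ConfusionMatrix(counts=matched, q=q, m_est=m_est)


def accuracy(est_labels, gt_labels) -> float:
    """Percentage of spikes on the matched confusion-matrix diagonal."""
    cm = confusion_matrix(est_labels, gt_labels)
    return 100.0 * cm.diagonal_sum / len(np.asarray(gt_labels))


def time_saved(C_t: float, P_t: float) -> float:
    """Time saved by the proposed mechanism: (C_t - P_t)/C_t * 100 percent."""
    if C_t <= 0:
        raise ValueError("conventional time C_t must be positive")
    if P_t < 0:
        raise ValueError("proposed time P_t must be non-negative")
    return (C_t - P_t) / C_t * 100.0


def accuracy_improvement(A_proposed: float, A_conventional: float) -> float:
    """Accuracy gain of proposed over conventional, in percentage points."""
    for v in (A_proposed, A_conventional):
        if not (0.0 <= v <= 100.0):
            raise ValueError("accuracies must lie in [0, 100]")
    return A_proposed - A_conventional
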