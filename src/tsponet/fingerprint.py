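"""Individual-level patient fingerprinting.

Each patient is assigned the diagnostic group of the single other patient
whose edge vector shows the highest Spearman correlation with theirs
(1-nearest-neighbour on rank correlation). Scans from the same subject are
excluded from the candidate pool. Performance is summarized as a confusion
matrix, per-group recall, and balanced accuracy, whose chance level is 1/K
for K groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import EdgeVector, rank_correlation_matrix

__all__ = ["FingerprintReport", "patient_fingerprint", "balanced_accuracy"]


@dataclass
class FingerprintReport:
    correlations: np.ndarray       # [n x n] Spearman, diagonal NaN
    assigned_group: np.ndarray
    best_match: np.ndarray         # candidate index per patient
    confusion: pd.DataFrame        # true group x assigned group
    per_group_recall: pd.Series
    balanced_accuracy: float
    chance_level: float
    ties: np.ndarray


def balanced_accuracy(confusion) -> float:
    """Mean over true classes of the per-class recall
    (diagonal / row sum)."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true class needs at least one sample")
    return float(np.mean(np.diag(cm) / row_sums))


def patient_fingerprint(edge_vectors, group_labels, subject_ids=None) -> FingerprintReport:
    """Nearest-correlation diagnostic assignment across a patient cohort.

    Parameters
    ----------
    edge_vectors : sequence of EdgeVector or 2-D array [n_patients x n_edges]
        Confound-residualized edges (or raw edges for the
        uncorrected-features sensitivity mode).
    group_labels : sequence of str
        True diagnostic group per patient.
    subject_ids : sequence, optional
        Scans sharing a subject id are excluded from each other's candidate
        pool (prevents trivial self-matching via retests).
    """
    if len(edge_vectors) and isinstance(edge_vectors[0], EdgeVector):
        mat = np.vstack([e.values for e in edge_vectors])
    else:
        mat = np.asarray(edge_vectors, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("fingerprinting requires at least 2 patients")
    groups = np.asarray(group_labels)
    if groups.size != n:
        raise ValueError("one group label per patient required")
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 diagnostic groups")
    if subject_ids is None:
        subject_ids = np.arange(n)
    subject_ids = np.asarray(subject_ids)

    for g in labels:
        if np.sum(groups == g) == 1:
            warnings.warn(f"group {g!r} has a single patient and no same-group "
                          "candidate; it can only be mismatched", UserWarning,
                          stacklevel=2)

    rho = rank_correlation_matrix(mat).astype(float)
    excluded = subject_ids[:, None] == subject_ids[None, :]
    rho_masked = np.where(excluded, -np.inf, rho)
    best = rho_masked.argmax(axis=1)
    ties = np.array([(rho_masked[i] == rho_masked[i, best[i]]).sum() > 1
                     for i in range(n)])
    assigned = groups[best]

    cm = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for g_true, g_pred in zip(groups, assigned):
        cm.loc[g_true, g_pred] += 1
    recall = pd.Series(np.diag(cm.to_numpy()) / cm.sum(axis=1).to_numpy(),
                       index=labels, name="recall")
    np.fill_diagonal(rho, np.nan)
    return FingerprintReport(
        correlations=rho, assigned_group=assigned, best_match=best,
        confusion=cm, per_group_recall=recall,
        balanced_accuracy=balanced_accuracy(cm.to_numpy()),
        chance_level=1.0 / len(labels), ties=ties)
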