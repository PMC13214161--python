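"""Biological specificity and test-retest reliability of similarity
networks.

Three analyses: (1) the blocking test — after partial pharmacological
occupancy of the target the spatial signal flattens, so the median
inter-regional similarity should rise (one-tailed Wilcoxon signed-rank on
per-subject medians); (2) edgewise ICC(3,1) — two-way mixed-effects,
single-measurement, consistency form — across test/retest sessions; (3)
connectome-style fingerprinting: each test scan should find its own retest
scan as the most rank-correlated among all retests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .network import EdgeVector, rank_correlation_matrix, to_edge_vector

__all__ = [
    "BlockingResult", "IccResult", "FingerprintMatchReport",
    "blocking_specificity", "edgewise_icc", "test_retest_fingerprint",
]


def _edge_values(obj) -> np.ndarray:
    if isinstance(obj, EdgeVector):
        return obj.values
    if hasattr(obj, "values") and getattr(obj, "values", None) is not None \
            and np.ndim(obj.values) == 2:
        return to_edge_vector(obj).values
    return np.asarray(obj, dtype=float)


@dataclass
class BlockingResult:
    baseline_medians: np.ndarray
    block_medians: np.ndarray
    p_value: float
    mean_pct_change: float
    n_subjects: int


def blocking_specificity(baseline, block) -> BlockingResult:
    """Compare per-subject median similarity before vs after target
    blockade.

    Parameters are matched sequences (same subject order) of similarity
    matrices or edge vectors. The test is a one-tailed Wilcoxon signed-rank
    with alternative "block > baseline", exact null for n <= 25, zero
    differences dropped.
    """
    base = np.array([np.median(_edge_values(m)) for m in baseline])
    blk = np.array([np.median(_edge_values(m)) for m in block])
    if base.size != blk.size:
        raise ValueError("baseline and block cohorts must be matched pairs")
    if base.size < 2:
        raise ValueError("need at least 2 matched pairs")
    diffs = blk - base
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero; no valid differences")
    method = "exact" if base.size <= 25 else "approx"
    stat = wilcoxon(blk, base, alternative="greater", zero_method="wilcox",
                    method=method)
    pct = 100.0 * (blk - base) / base
    return BlockingResult(baseline_medians=base, block_medians=blk,
                          p_value=float(stat.pvalue),
                          mean_pct_change=float(np.mean(pct)),
                          n_subjects=int(base.size))


@dataclass
class IccResult:
    icc: np.ndarray           # per edge, consistency ICC(3,1)
    median: float
    mad: float

    @property
    def n_edges(self) -> int:
        return self.icc.size


def edgewise_icc(test_edges, retest_edges) -> IccResult:
    """Edgewise ICC(3,1): two-way mixed effects, single measurement,
    consistency.

    For each edge, with n subjects and k=2 sessions,
    ICC = (MSR - MSE) / (MSR + (k-1) MSE) from the two-way ANOVA
    decomposition (subjects as random rows, sessions as fixed columns).
    Edges with no variance in either decomposition are returned as NaN and
    excluded from the median/MAD summary.
    """
    t = np.vstack([_edge_values(v) for v in test_edges]).astype(float)
    r = np.vstack([_edge_values(v) for v in retest_edges]).astype(float)
    if t.shape != r.shape:
        raise ValueError("test and retest cohorts must have matching shapes")
    n = t.shape[0]
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    k = 2
    data = np.stack([t, r], axis=1)            # [n, k, E]
    grand = data.mean(axis=(0, 1))             # [E]
    subj_mean = data.mean(axis=1)              # [n, E]
    sess_mean = data.mean(axis=0)              # [k, E]
    ssr = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((sess_mean - grand) ** 2).sum(axis=0)
    sst = ((data - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msr - mse) / denom, np.nan)
    valid = icc[np.isfinite(icc)]
    if valid.size == 0:
        raise ValueError("ICC undefined for every edge (no variance)")
    med = float(np.median(valid))
    mad = float(np.median(np.abs(valid - med)))
    return IccResult(icc=icc, median=med, mad=mad)


@dataclass
class FingerprintMatchReport:
    accuracy: float
    predicted: np.ndarray      # index into retest cohort per test scan
    true_match_rank: np.ndarray  # 1 = top match
    correlations: np.ndarray   # [n_test, n_retest] Spearman rho
    ties: np.ndarray           # bool per test scan


def test_retest_fingerprint(test_edges, retest_edges,
                            method: str = "spearman") -> FingerprintMatchReport:
    """Identify each test scan's retest by maximal correlation.

    The i-th test and i-th retest vector belong to the same subject.
    ``method`` is ``"spearman"`` (default, rank-based) or ``"pearson"``.
    Ties at the argmax break to the lowest candidate index and are flagged.
    """
    t = np.vstack([_edge_values(v) for v in test_edges]).astype(float)
    r = np.vstack([_edge_values(v) for v in retest_edges]).astype(float)
    if t.shape != r.shape:
        raise ValueError("test and retest cohorts must have matching shapes")
    n = t.shape[0]
    if n < 2:
        raise ValueError("fingerprinting requires at least 2 paired scans")
    if method == "spearman":
        full = rank_correlation_matrix(np.vstack([t, r]))
    elif method == "pearson":
        full = np.corrcoef(np.vstack([t, r]))
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    rho = full[:n, n:]
    predicted = rho.argmax(axis=1)
    ties = np.array([(rho[i] == rho[i, predicted[i]]).sum() > 1 for i in range(n)])
    # rank of the true match among candidates, 1-based
    order = (-rho).argsort(axis=1, kind="stable")
    rank = np.empty(n, dtype=int)
    for i in range(n):
        rank[i] = int(np.flatnonzero(order[i] == i)[0]) + 1
    accuracy = float(np.mean(predicted == np.arange(n)))
    return FingerprintMatchReport(accuracy=accuracy, predicted=predicted,
                                  true_match_rank=rank, correlations=rho,
                                  ties=ties)
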