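"""Scoring of estimated networks against ground truth.

Edge recovery is scored per time point by precision, recall and F1 against
the true support (nonzero pattern only, not weights); the dynamics test is
scored by detection power, the percentage of benchmark-dynamic pairs that a
method flags.  Method comparisons use a two-sided permutation test on score
means, and cross-method similarity is the Pearson correlation of mean
network upper triangles over a significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import vectorize_upper

__all__ = [
    "EdgeSets",
    "ScoreSeries",
    "edge_sets_from_theta",
    "precision_recall_f1",
    "f1_from_counts",
    "confusion_counts",
    "detection_power",
    "matrix_similarity",
    "permutation_compare",
]


@dataclass(frozen=True)
class EdgeSets:
    """Per-timepoint sets of i<j node pairs."""

    sets: tuple[frozenset, ...]

    def __len__(self):
        return len(self.sets)


@dataclass(frozen=True)
class ScoreSeries:
    """Precision/recall/F1 over aligned time points with summary statistics."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    @property
    def mean_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def sd_f1(self) -> float:
        return float(self.f1.std(ddof=1)) if self.f1.size > 1 else 0.0


def edge_sets_from_theta(theta: np.ndarray, tol: float = 1e-8) -> EdgeSets:
    """Edge sets of a (T, p, p) stack: pairs with |weight| above tolerance."""
    theta = np.asarray(theta)
    p = theta.shape[1]
    iu = np.triu_indices(p, k=1)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    out = []
    for t in range(theta.shape[0]):
        mask = np.abs(theta[t][iu]) > tol
        out.append(frozenset(pr for pr, m in zip(pairs, mask) if m))
    return EdgeSets(sets=tuple(out))


def _prf(n_tp: int, n_est: int, n_true: int) -> tuple[float, float, float]:
    """Empty-set conventions: no estimated edges with nonempty truth gives
    precision 0 (hence F1 0); both sets empty counts as a perfect F1 of 1."""
    if n_est == 0 and n_true == 0:
        return 1.0, 1.0, 1.0
    pre = n_tp / n_est if n_est else 0.0
    rec = n_tp / n_true if n_true else 0.0
    f1 = 2 * pre * rec / (pre + rec) if (pre + rec) else 0.0
    return pre, rec, f1


def precision_recall_f1(est: EdgeSets, truth: EdgeSets) -> ScoreSeries:
    """Per-timepoint Pre = |E∩T|/|E|, Rec = |E∩T|/|T|, F1 = harmonic mean."""
    if len(est) != len(truth):
        raise ValueError("estimated and true edge sets must cover the same time points")
    pre, rec, f1 = [], [], []
    for e, t in zip(est.sets, truth.sets):
        a, b, c = _prf(len(e & t), len(e), len(t))
        pre.append(a)
        rec.append(b)
        f1.append(c)
    return ScoreSeries(precision=np.array(pre), recall=np.array(rec), f1=np.array(f1))


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 from pooled confusion counts."""
    return _prf(tp, tp + fp, tp + fn)[2]


def confusion_counts(est: EdgeSets, truth: EdgeSets, p: int):
    """Pooled TP/FP/FN/TN over all pairs and time points."""
    if len(est) != len(truth):
        raise ValueError("time points must align")
    n_pairs = p * (p - 1) // 2
    tp = fp = fn = 0
    for e, t in zip(est.sets, truth.sets):
        tp += len(e & t)
        fp += len(e - t)
        fn += len(t - e)
    total = n_pairs * len(est)
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def detection_power(flagged: np.ndarray, dynamic: np.ndarray) -> float:
    """100 x fraction of benchmark-dynamic pairs that were flagged."""
    flagged = np.asarray(flagged, bool)
    dynamic = np.asarray(dynamic, bool)
    n_dyn = int(dynamic.sum())
    if n_dyn == 0:
        raise ValueError("benchmark has no dynamic pairs; power is undefined")
    return 100.0 * float((flagged & dynamic).sum()) / n_dyn


def matrix_similarity(meanA: np.ndarray, meanB: np.ndarray, mask: np.ndarray) -> float:
    """Pearson r between vectorised upper triangles over a significance mask.

    ``mask`` is a symmetric boolean matrix (union of each method's
    significant edges); entries significant in only one method contribute
    their zeros in the other.
    """
    a = vectorize_upper(np.asarray(meanA, float))
    b = vectorize_upper(np.asarray(meanB, float))
    m = vectorize_upper(np.asarray(mask, float)) > 0.5
    if m.sum() < 3:
        raise ValueError("need at least three masked entries for a correlation")
    r, _ = stats.pearsonr(a[m], b[m])
    return float(r)


def permutation_compare(
    scoresA: np.ndarray, scoresB: np.ndarray, n_iter: int = 100_000, seed=None
) -> float:
    """Two-sided permutation test on the difference in means (add-one rule)."""
    a = np.asarray(scoresA, float)
    b = np.asarray(scoresB, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n = a.size
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(pooled)
        if abs(perm[:n].mean() - perm[n:].mean()) >= obs - 1e-15:
            count += 1
    return (1 + count) / (1 + n_iter)


def matrix_cell_scores(est_support: np.ndarray, true_support: np.ndarray) -> ScoreSeries:
    """Precision/recall/F1 counted over all p^2 adjacency-matrix cells.

    Both the estimate and the truth mark the diagonal as connected (every
    estimator trivially models a region's dependence on its own past, and the
    generating process carries positive self-coupling), so a confusion matrix
    over T time points has T * p^2 cells, so a W-window benchmark yields
    confusion totals of W x p^2.  The pair-based :func:`precision_recall_f1`
    excludes the diagonal and counts each undirected pair once.
    """
    e = np.asarray(est_support, bool).copy()
    t = np.asarray(true_support, bool).copy()
    if e.shape != t.shape or e.ndim != 3:
        raise ValueError("need aligned (T, p, p) boolean stacks")
    p = e.shape[1]
    idx = np.arange(p)
    e[:, idx, idx] = True
    t[:, idx, idx] = True
    pre, rec, f1 = [], [], []
    for k in range(e.shape[0]):
        tp = int((e[k] & t[k]).sum())
        a, b, c = _prf(tp, int(e[k].sum()), int(t[k].sum()))
        pre.append(a)
        rec.append(b)
        f1.append(c)
    return ScoreSeries(precision=np.array(pre), recall=np.array(rec), f1=np.array(f1))
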