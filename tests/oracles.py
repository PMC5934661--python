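"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, O(n*m) scans, power
iteration) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def power_iteration(mat: np.ndarray, tol: float = 1e-14, max_iter: int = 200_000
                    ) -> tuple[np.ndarray, float]:
    """Lead eigenpair of a symmetric PSD matrix by plain power iteration."""
    mat = np.asarray(mat, dtype=float)
    rng = np.random.default_rng(12345)
    v = rng.standard_normal(mat.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = mat @ v
        lam = float(np.linalg.norm(w))
        w /= lam
        if w @ v < 0:
            w = -w
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    if v.sum() < 0:
        v = -v
    return v, lam


def brute_force_auc(scores, labels) -> float:
    """AUC as the fraction of (positive, negative) pairs ordered correctly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exact_wilcoxon_p(a, b) -> float:
    """Two-sided rank-sum p by full enumeration of label assignments (no ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks = pooled.argsort().argsort() + 1
    n1 = len(a)
    observed = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)], dtype=float)
    mean = sums.mean()
    extreme = np.sum(np.abs(sums - mean) >= np.abs(observed - mean) - 1e-9)
    return float(extreme / len(sums))


def brute_force_overlap(pos_1based: int, intervals) -> list[str]:
    """All labels of 0-based half-open intervals containing a 1-based position."""
    p = pos_1based - 1
    return sorted(
        (label for _c, s, e, label in intervals if s <= p < e),
        key=str,
    )


def column_mean_impute(X: np.ndarray) -> np.ndarray:
    out = np.asarray(X, dtype=float).copy()
    means = np.nanmean(out, axis=0)
    for j in range(out.shape[1]):
        col = out[:, j]
        col[np.isnan(col)] = means[j]
    return out
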