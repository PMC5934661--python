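"""Benchmarking statistics: ROC/AUC, Wilcoxon rank-sum, combined p, coverage.

These are the standard tools for asking whether a score separates a
functional class (pathogenic, trait-associated, recurrent) from its control
class, plus Wilkinson's order-statistic method for combining the per-variant
significance levels of a class into one p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ScoreMatrix, ValidationError


@dataclass
class LabeledScores:
    """Scores paired with binary labels (1 = functional class, 0 = control)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValidationError("scores and labels must be equal-length 1-D vectors")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    ls = LabeledScores(np.asarray(scores, dtype=float), np.asarray(labels))
    pos = ls.scores[ls.labels == 1]
    neg = ls.scores[ls.labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be nonempty")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    pos, neg = _split(scores, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
           level: float = 0.95) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the AUC.

    Resampling is stratified by class so every resample keeps both classes.
    """
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("need at least 2 scores per class for a bootstrap CI")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    labs = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        aucs[b] = roc_auc(np.concatenate([bp, bn]), labs)
    tail = (1.0 - level) / 2.0
    lo, hi = np.percentile(aucs, [100 * tail, 100 * (1 - tail)])
    return float(lo), float(hi)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration for small tie-free samples (total n <= 12), else the
    normal approximation with tie and continuity corrections. Returns the
    Mann-Whitney U of the first sample and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilkinson_combined_p(pvals, r: int = 1) -> float:
    """Wilkinson's method: combine p-values through their r-th smallest.

    Under the global null the r-th order statistic of k uniform p-values is
    Beta(r, k - r + 1); the combined p is that Beta CDF evaluated at the
    observed r-th smallest p. r = 1 reduces to 1 - (1 - p_min)^k.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    k = p.size
    if not (1 <= r <= k):
        raise ValidationError(f"r must be in [1, {k}], got {r}")
    return float(stats.beta.cdf(p[r - 1], r, k - r + 1))


def coverage_report(matrix: ScoreMatrix) -> pd.Series:
    """Fraction of variants with an observed (pre-imputation) value per system.

    The ``any`` entry is the fraction of variants observed by at least one
    system.
    """
    obs = ~np.isnan(matrix.values)
    n = max(matrix.n_variants, 1)
    per_system = obs.sum(axis=0) / n
    out = pd.Series(per_system, index=matrix.systems, dtype=float)
    out["any"] = float(obs.any(axis=1).sum() / n)
    return out
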