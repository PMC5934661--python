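"""Scoring of query variants against a trained model.

A query score table goes through the same pipeline the training set did:
per-system transforms, imputation of missing cells (merged with the model's
complete-case reference pool), linear rescaling of each observed raw score
onto the training scale, the weighted-sum integrated score, an upper-tail
p-value against the training null, and a rank within the query set.

Observed raw values are mapped to the training-standardized scale by the
linear map that sends the training minimum/maximum of the raw scores to the
minimum/maximum of their standardized counterparts; being linear, it
extrapolates for query values outside the training range (novel mutations can
exceed it), and extrapolated cells are counted in a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imputation import ImputationConfig, impute_query
from .io import ScoreMatrix, ValidationError, VariantKey
from .training import NullDistribution, RescaleParams, TrainedModel, WeightVector, apply_transforms
from .workflows import WORKFLOWS


@dataclass
class ScoredVariant:
    """One query variant with its rescaled panel, integrated score, p and rank."""

    key: VariantKey
    rescaled: dict[str, float]
    iw_score: float
    p_value: float
    rank: int
    imputed_systems: tuple[str, ...]
    significant: bool | None = None


def rescale_query(m, params: RescaleParams):
    """Map a raw query score onto the training-standardized scale.

    The map is the unique linear function taking the training minimum and
    maximum of the raw scores to the minimum and maximum of the standardized
    training scores; it therefore preserves the relative position
    (Max_A - m)/(m - Min_A) = (Max_R - x)/(x - Min_R) and extrapolates
    linearly outside the training range.
    """
    m = np.asarray(m, dtype=float)
    span = params.max_a - params.min_a
    x = (params.max_r * (m - params.min_a) + params.min_r * (params.max_a - m)) / span
    # anchor the training endpoints exactly (the quotient can be off by 1 ulp)
    x = np.where(m == params.min_a, params.min_r, x)
    x = np.where(m == params.max_a, params.max_r, x)
    return float(x) if x.ndim == 0 else x


def iw_score(x: np.ndarray, weights: WeightVector | np.ndarray) -> float:
    """Weighted sum of rescaled system scores (the integrated score)."""
    x = np.asarray(x, dtype=float)
    w = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, dtype=float)
    if x.shape[-1] != w.shape[0]:
        raise ValidationError(f"score vector has {x.shape[-1]} systems, weights have {w.shape[0]}")
    if np.isnan(x).any():
        raise ValidationError("residual missing values in rescaled scores; impute first")
    return x @ w


def p_value(score, null: NullDistribution):
    """Upper-tail probability of an integrated score under the training null."""
    return null.p_value(score)


def local_significance(target_score: float, background_scores) -> float:
    """Significance of one score against the scores of nearby variants.

    The target is z-scored against the mean and standard deviation of the
    local background and mapped to an upper-tail standard-normal probability.
    Suited to questions like "is this variant exceptional within its locus?",
    in contrast to the genome-wide training null.
    """
    bg = np.asarray(background_scores, dtype=float)
    if bg.ndim != 1 or len(bg) < 3:
        raise ValidationError("need at least 3 background scores")
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValidationError("background scores have zero variance")
    z = (float(target_score) - bg.mean()) / sd
    return float(stats.norm.sf(z))


def _rank_order(iw: np.ndarray, keys: list[VariantKey]) -> np.ndarray:
    """Ranks 1..n by descending score; ties broken by (chrom, pos, ref, alt)."""
    order = sorted(range(len(keys)), key=lambda i: (-iw[i], keys[i]))
    ranks = np.empty(len(keys), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def score_variants(matrix: ScoreMatrix, model: TrainedModel, alpha: float | None = None,
                   seed: int = 0, n_imputations: int = 10) -> list[ScoredVariant]:
    """Score a raw query score matrix against a trained model.

    Missing cells are allowed and imputed against the model's reference pool;
    a model system whose query column is entirely missing is an error (for
    GWAVA systems on novel variants, switch to an N workflow). Results are
    returned in input order; ``rank`` orders them by descending integrated
    score with genomic-coordinate tie-breaks. ``alpha`` (strict ``p < alpha``)
    fills the ``significant`` flag.
    """
    absent = [s for s in model.systems if s not in matrix.systems]
    if absent:
        known_only = [s for s in absent if any(sp.id == s and sp.known_only for sp in model.system_specs)]
        hint = (" (these systems score known variants only; use workflow N8 or N6 for novel variants)"
                if known_only else "")
        raise ValidationError(f"query lacks model system(s): {', '.join(absent)}{hint}")
    sub = matrix.subset_systems(list(model.systems))

    # canonical row order inside the pipeline makes results exactly invariant
    # to the input row order; undone before returning
    canon = sorted(range(sub.n_variants), key=lambda i: sub.variants[i])
    sub = ScoreMatrix([sub.variants[i] for i in canon], list(sub.systems),
                      sub.values[canon].copy())
    inverse = np.argsort(canon)

    all_missing = [s for s, col in zip(sub.systems, np.isnan(sub.values).T) if col.all()]
    if all_missing:
        known_only = [s for s in all_missing
                      if any(sp.id == s and sp.known_only for sp in model.system_specs)]
        hint = (" (use workflow N8 or N6 for novel variants)" if known_only else "")
        raise ValidationError(
            f"query column(s) entirely missing: {', '.join(all_missing)}{hint}"
        )

    transformed = apply_transforms(sub, {sp.id: sp for sp in model.system_specs})

    rescaled = transformed.values.copy()
    n_extrapolated = 0
    for j, sid in enumerate(transformed.systems):
        p = model.rescale_params[sid]
        col = rescaled[:, j]
        obs = ~np.isnan(col)
        n_extrapolated += int(np.sum((col[obs] < p.min_a) | (col[obs] > p.max_a)))
        col[obs] = rescale_query(col[obs], p)
    if n_extrapolated:
        warnings.warn(
            f"{n_extrapolated} query cell(s) fall outside the training score range "
            "and were linearly extrapolated",
            stacklevel=2,
        )

    cfg = ImputationConfig(n_imputations=n_imputations, seed=seed)
    completed, mask = impute_query(rescaled, model.reference_pool, cfg)

    iw = completed @ model.weights.values
    pvals = np.atleast_1d(model.null.p_value(iw))
    ranks = _rank_order(iw, sub.variants)

    out: list[ScoredVariant] = []
    for i in inverse:  # back to input order
        key = sub.variants[i]
        imputed = tuple(s for s, flag in zip(sub.systems, mask[i]) if flag)
        out.append(ScoredVariant(
            key=key,
            rescaled={s: float(completed[i, j]) for j, s in enumerate(sub.systems)},
            iw_score=float(iw[i]),
            p_value=float(pvals[i]),
            rank=int(ranks[i]),
            imputed_systems=imputed,
            significant=None if alpha is None else bool(pvals[i] < alpha),
        ))
    return out
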