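"""Model training: transforms, standardization, lead-eigenvector weights, null fit.

The weighting scheme is unsupervised and spectral. After per-system
transforms and standardization to mean 0 / variance 1 on the training set,
the covariance of the standardized columns — computed literally as the matrix
of pairwise-complete Pearson correlations, so that variants with partial
score coverage still contribute — is eigendecomposed, and the eigenvector of
the largest eigenvalue supplies the per-system weights W_i. The integrated
score of a variant is then the weighted sum over its rescaled system scores.
Under conditional independence of the systems given a variant's true
functional state, systems that track the shared latent signal most strongly
load most on the lead eigenvector, so the weights favour informative,
mutually corroborating systems without any labelled training data.

Significance of an integrated score is read off the distribution of training
scores, modelled as a shifted (three-parameter) lognormal fitted by maximum
likelihood; the empirical quantiles of the training scores are retained as a
distribution-free fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputationConfig, multiple_impute
from .io import IwScoringError, ScoreMatrix, SystemSpec, ValidationError, system_spec
from .workflows import workflow_systems


@dataclass(frozen=True)
class RescaleParams:
    """Per-system training scale: original and rescaled min/max plus mean/sd."""

    min_a: float
    max_a: float
    min_r: float
    max_r: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.max_a > self.min_a):
            raise ValidationError("max_a must exceed min_a")
        if not (self.max_r > self.min_r):
            raise ValidationError("max_r must exceed min_r")


@dataclass(frozen=True)
class WeightVector:
    """Unit-norm lead-eigenvector weights over the active systems."""

    systems: tuple[str, ...]
    values: np.ndarray
    lead_eigenvalue: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.systems), name="weight")


@dataclass
class NullDistribution:
    """Null model for integrated scores: shifted lognormal or empirical quantiles.

    The shift makes the support positive (training scores straddle zero);
    ``meanlog``/``sdlog`` are the ML parameters of log(score + shift). The
    sorted training scores are always retained so the empirical fallback is
    available after a model round trip.
    """

    family: str
    shift: float
    meanlog: float
    sdlog: float
    sorted_scores: np.ndarray
    train_mean: float
    train_sd: float

    def p_value(self, score) -> np.ndarray | float:
        """Upper-tail probability of ``score`` under the null; in (0, 1]."""
        score = np.asarray(score, dtype=float)
        scalar = score.ndim == 0
        score = np.atleast_1d(score)
        if self.family == "shifted_lognormal":
            shifted = score + self.shift
            p = np.ones_like(score)
            ok = shifted > 0
            z = (np.log(shifted[ok]) - self.meanlog) / self.sdlog
            p[ok] = stats.norm.sf(z)
        elif self.family == "empirical":
            n = len(self.sorted_scores)
            # r = count of training scores >= score; p = (r + 1) / (N + 1)
            r = n - np.searchsorted(self.sorted_scores, score, side="left")
            p = (r + 1) / (n + 1)
        else:
            raise ValidationError(f"unknown null family {self.family!r}")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        return float(p[0]) if scalar else p


@dataclass
class TrainedModel:
    """Everything needed to score a query set against the training reference."""

    workflow_id: str
    system_specs: tuple[SystemSpec, ...]
    rescale_params: dict[str, RescaleParams]
    weights: WeightVector
    null: NullDistribution
    reference_pool: np.ndarray  # complete-case standardized rows, systems order

    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.system_specs)


DEFAULT_P_FLOOR = 1e-16


def apply_transforms(matrix: ScoreMatrix, system_specs: dict[str, SystemSpec] | None = None,
                     p_floor: float = DEFAULT_P_FLOOR) -> ScoreMatrix:
    """Apply per-system transforms; currently -log2 for p-value-valued systems.

    ``neg_log2_p`` values must be probabilities in (0, 1]; they are floored at
    ``p_floor`` before the log so vanishing p-values stay finite. Missing
    cells pass through untouched.
    """
    out = matrix.copy()
    for j, sid in enumerate(out.systems):
        spec = (system_specs or {}).get(sid) or system_spec(sid)
        if spec.transform == "identity":
            continue
        col = out.values[:, j]
        obs = ~np.isnan(col)
        if np.any((col[obs] <= 0) | (col[obs] > 1)):
            raise ValidationError(
                f"system {sid!r} uses the neg_log2_p transform but has values outside (0, 1]"
            )
        col[obs] = -np.log2(np.maximum(col[obs], p_floor))
    return out


def standardize_training(matrix: ScoreMatrix) -> tuple[ScoreMatrix, dict[str, RescaleParams]]:
    """Standardize each column to mean 0 / variance 1 over its observed values.

    The sample standard deviation (n-1 denominator) is used. The min/max of
    the original and of the standardized values are recorded per system; they
    anchor the linear rescaling of query scores onto the training scale.
    """
    out = matrix.copy()
    params: dict[str, RescaleParams] = {}
    for j, sid in enumerate(out.systems):
        col = out.values[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            raise ValidationError(f"system {sid!r} has fewer than 2 observed values")
        x = col[obs]
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0.0:
            raise ValidationError(f"zero variance: {sid}")
        rescaled = (x - mean) / sd
        col[obs] = rescaled
        params[sid] = RescaleParams(
            min_a=float(np.min(x)),
            max_a=float(np.max(x)),
            min_r=float(np.min(rescaled)),
            max_r=float(np.max(rescaled)),
            mean=mean,
            sd=sd,
        )
    return out, params


def pairwise_correlation(matrix: ScoreMatrix, min_joint: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the score columns.

    Each entry uses exactly the variants where both systems are observed, so
    partial coverage still informs the estimate. Pairs with fewer than
    ``min_joint`` joint observations are an error.
    """
    obs = ~np.isnan(matrix.values)
    joint = obs.T.astype(np.int64) @ obs.astype(np.int64)
    k = len(matrix.systems)
    for i in range(k):
        for j in range(i + 1, k):
            if joint[i, j] < min_joint:
                raise ValidationError(
                    f"systems {matrix.systems[i]!r} and {matrix.systems[j]!r} share only "
                    f"{joint[i, j]} jointly observed variants (need >= {min_joint})"
                )
    df = pd.DataFrame(matrix.values, columns=matrix.systems)
    corr = df.corr(method="pearson", min_periods=min_joint).to_numpy()
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.systems, columns=matrix.systems)


def estimate_weights(correlation: pd.DataFrame | np.ndarray,
                     eig_gap_tol: float = 1e-12) -> WeightVector:
    """Lead eigenvector of the correlation matrix, the system weights.

    The eigenvector is unit Euclidean norm with its sign fixed so the
    component sum is positive. A (near-)tied lead eigenvalue has no unique
    lead eigenvector and is reported as an error rather than resolved
    arbitrarily.
    """
    if isinstance(correlation, pd.DataFrame):
        systems = tuple(str(c) for c in correlation.columns)
        mat = correlation.to_numpy(dtype=float)
    else:
        mat = np.asarray(correlation, dtype=float)
        systems = tuple(f"s{i}" for i in range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.all(np.isfinite(mat)):
        raise ValidationError("correlation matrix contains non-finite entries")
    if np.abs(mat - mat.T).max() > 1e-8:
        raise ValidationError("correlation matrix is not symmetric (asymmetry > 1e-8)")
    eigvals, eigvecs = np.linalg.eigh((mat + mat.T) / 2.0)
    if mat.shape[0] > 1 and (eigvals[-1] - eigvals[-2]) < eig_gap_tol:
        raise ValidationError(
            "lead eigenvalue is tied; the weight direction is not unique — "
            "perturb the inputs or drop a redundant system"
        )
    w = eigvecs[:, -1]
    total = w.sum()
    if total < 0:
        w = -w
    elif total == 0:
        raise ValidationError("lead eigenvector components sum to zero; sign is undefined")
    return WeightVector(systems, w.copy(), float(eigvals[-1]))


def fit_null(scores: np.ndarray, family: str = "shifted_lognormal") -> NullDistribution:
    """Fit the null distribution of training integrated scores.

    Integrated scores straddle zero, so a plain lognormal cannot describe
    them; a shifted (three-parameter) lognormal is fitted by maximum
    likelihood over shift, meanlog and sdlog. If the location fit fails or
    places the support boundary inside the data, the shift falls back to
    -min(scores) + eps (eps = 1e-6 x score range) with meanlog/sdlog the ML
    moments of log(score + shift) — slightly biased but always defined. The
    sorted scores are kept for the empirical fallback, whose p-value for a
    score beating all N training scores is 1/(N+1).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 100:
        raise ValidationError("need at least 100 training scores to fit a null")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        raise ValidationError("training scores are constant; no null can be fitted")
    if family not in ("shifted_lognormal", "empirical"):
        raise ValidationError(f"unknown null family {family!r}")

    shift = meanlog = sdlog = None
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            shape, loc, scale = stats.lognorm.fit(scores)
        if np.all(np.isfinite([shape, loc, scale])) and loc < lo and shape > 0 and scale > 0:
            shift, meanlog, sdlog = -loc, float(np.log(scale)), float(shape)
    except Exception:  # the optimizer can fail on awkward shapes; fall back
        pass
    if shift is None:
        eps = 1e-6 * (hi - lo)
        shift = -lo + eps
        logs = np.log(scores + shift)
        meanlog = float(logs.mean())
        sdlog = float(logs.std(ddof=0))

    return NullDistribution(
        family=family,
        shift=float(shift),
        meanlog=meanlog,
        sdlog=sdlog,
        sorted_scores=np.sort(scores),
        train_mean=float(scores.mean()),
        train_sd=float(scores.std(ddof=1)),
    )


def train(matrix: ScoreMatrix, workflow_id: str, seed: int,
          n_imputations: int = 10, reference_size: int = 100_000,
          null_family: str = "shifted_lognormal",
          p_floor: float = DEFAULT_P_FLOOR,
          system_specs: dict[str, SystemSpec] | None = None) -> TrainedModel:
    """Train a model on a raw training score matrix for one workflow preset.

    Pipeline: restrict to the workflow's systems, transform, standardize,
    pairwise-complete correlation, lead-eigenvector weights; then complete the
    standardized matrix by EMB multiple imputation, compute training
    integrated scores, fit the null, and retain a seeded complete-case
    reference pool (up to ``reference_size`` rows) for query imputation.
    Deterministic: the same seed reproduces the model bit for bit.

    ``system_specs`` overrides the canonical per-system transforms, e.g. for
    tables whose columns are already on the integration scale.
    """
    active = workflow_systems(workflow_id)
    sub = matrix.subset_systems(active)
    if system_specs is None:
        specs = tuple(system_spec(s) for s in active)
    else:
        specs = tuple(system_specs.get(s) or system_spec(s) for s in active)
    transformed = apply_transforms(sub, {sp.id: sp for sp in specs}, p_floor=p_floor)
    standardized, rescale = standardize_training(transformed)
    corr = pairwise_correlation(standardized)
    weights = estimate_weights(corr)

    ss = np.random.SeedSequence(seed)
    imp_seed, pool_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    cfg = ImputationConfig(n_imputations=n_imputations, seed=imp_seed,
                           reference_size=reference_size)
    completed, _mask = multiple_impute(standardized.values, cfg)
    train_scores = completed @ weights.values
    null = fit_null(train_scores, family=null_family)

    complete_rows = np.nonzero(~np.isnan(standardized.values).any(axis=1))[0]
    if complete_rows.size == 0:
        raise ValidationError("no complete-case rows available for the reference pool")
    n_pool = min(reference_size, complete_rows.size)
    pool_rng = np.random.default_rng(pool_seed)
    chosen = np.sort(pool_rng.choice(complete_rows, size=n_pool, replace=False))
    pool = standardized.values[chosen].copy()

    return TrainedModel(
        workflow_id=workflow_id,
        system_specs=specs,
        rescale_params=rescale,
        weights=weights,
        null=null,
        reference_pool=pool,
    )


def weight_stability(matrix: ScoreMatrix, fractions=(0.2, 0.4, 0.6, 0.8),
                     n_repeats: int = 5, seed: int = 0,
                     p_floor: float = DEFAULT_P_FLOOR,
                     system_specs: dict[str, SystemSpec] | None = None) -> pd.DataFrame:
    """Re-estimate weights on random row subsets and report their deviation.

    For every fraction and repeat, rows are subsampled without replacement and
    the weights re-estimated; the report carries the per-system absolute
    deviation from the full-data weights and their maximum. A subsample that
    violates the correlation preconditions is flagged (``ok`` False), not
    fatal. One row per (fraction, repeat).
    """
    fractions = tuple(float(f) for f in fractions)
    if any(not (0 < f <= 1) for f in fractions):
        raise ValidationError("fractions must lie in (0, 1]")
    transformed = apply_transforms(matrix, system_specs, p_floor=p_floor)
    full = estimate_weights(pairwise_correlation(transformed))
    rng = np.random.default_rng(seed)
    n = matrix.n_variants
    records = []
    for frac in fractions:
        size = max(int(round(frac * n)), 1)
        for rep in range(n_repeats):
            if size == n:
                idx = np.arange(n)
            else:
                idx = rng.choice(n, size=size, replace=False)
            sub = ScoreMatrix([matrix.variants[i] for i in idx], list(matrix.systems),
                              transformed.values[idx].copy())
            rec = {"fraction": frac, "repeat": rep, "n_rows": size, "ok": True}
            try:
                w = estimate_weights(pairwise_correlation(sub))
                dev = np.abs(w.values - full.values)
                rec["max_abs_dev"] = float(dev.max())
                rec.update({f"dev_{s}": float(d) for s, d in zip(full.systems, dev)})
            except (ValidationError, IwScoringError):
                rec["ok"] = False
                rec["max_abs_dev"] = np.nan
                rec.update({f"dev_{s}": np.nan for s in full.systems})
            records.append(rec)
    return pd.DataFrame.from_records(records)
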