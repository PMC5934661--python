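"""Multiple imputation of missing scores by EM with bootstrapping (EMB).

The score panel is modelled as a single multivariate normal with an ignorable
(MCAR/MAR) missingness mechanism. Each of ``n_imputations`` completions
bootstraps the rows, fits the normal by expectation-maximization on the
bootstrap sample, and draws every missing cell from its conditional normal
given the row's observed cells (conditional mean plus conditional-variance
noise, i.e. proper imputation). The final imputed value is the mean over the
completions; observed cells are never altered.

Small query sets are imputed by stacking them on a large complete-case
reference pool drawn from the training set, which stabilizes the estimated
mean and covariance (:func:`impute_query`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IwScoringError, ValidationError


class ImputationError(IwScoringError):
    """EM failed to converge or the missingness pattern is unidentifiable."""


@dataclass
class ImputationConfig:
    """Tuning knobs for EMB imputation.

    ``ridge`` is a small diagonal regularizer added to the fitted covariance;
    ``None`` means 1e-6 x mean diagonal, which guards the near-singular
    covariances that bootstrap samples of strongly correlated score blocks
    frequently produce.
    """

    n_imputations: int = 10
    seed: int = 0
    reference_size: int = 100_000
    max_em_iters: int = 200
    em_tol: float = 1e-5
    ridge: float | None = None

    def __post_init__(self) -> None:
        if self.n_imputations < 1:
            raise ValidationError("n_imputations must be >= 1")
        if self.em_tol <= 0:
            raise ValidationError("em_tol must be positive")
        if self.ridge is not None and self.ridge < 0:
            raise ValidationError("ridge must be >= 0")


def _check_identifiable(mask_obs: np.ndarray) -> None:
    k = mask_obs.shape[1]
    counts = mask_obs.sum(axis=0)
    thin = np.nonzero(counts < 2)[0]
    if thin.size:
        raise ValidationError(f"column(s) {thin.tolist()} have fewer than 2 observed values")
    joint = mask_obs.T.astype(np.int64) @ mask_obs.astype(np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            if joint[i, j] == 0:
                raise ImputationError(
                    f"columns {i} and {j} are never jointly observed; "
                    "the covariance between them is unidentifiable"
                )


def _patterns(missing: np.ndarray):
    """Group row indices by missingness pattern; yields (row_idx, miss_bool)."""
    uniq, inverse = np.unique(missing, axis=0, return_inverse=True)
    for g in range(uniq.shape[0]):
        yield np.nonzero(inverse == g)[0], uniq[g]


def _ridge_value(X: np.ndarray, config: ImputationConfig) -> float:
    if config.ridge is not None:
        return config.ridge
    col_var = np.nanvar(X, axis=0)
    return 1e-6 * float(np.mean(col_var)) if np.all(np.isfinite(col_var)) else 1e-6


def em_fit(X: np.ndarray, config: ImputationConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood mean and covariance of a multivariate normal with NaNs.

    Complete data short-circuits to the sample mean and (n-denominator)
    covariance. Returns ``(mean, covariance)``; the covariance includes the
    configured ridge on its diagonal.
    """
    config = config or ImputationConfig()
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    missing = np.isnan(X)
    _check_identifiable(~missing)
    ridge = _ridge_value(X, config)

    if not missing.any():
        mu = X.mean(axis=0)
        sigma = np.cov(X, rowvar=False, ddof=0).reshape(k, k) + ridge * np.eye(k)
        return mu, sigma

    mu = np.nanmean(X, axis=0)
    sigma = np.diag(np.nanvar(X, axis=0) + ridge)
    groups = list(_patterns(missing))

    for iteration in range(1, config.max_em_iters + 1):
        s1 = np.zeros(k)
        s2 = np.zeros((k, k))
        for rows, miss in groups:
            Xp = X[rows]
            if not miss.any():
                s1 += Xp.sum(axis=0)
                s2 += Xp.T @ Xp
                continue
            o = ~miss
            m = miss
            soo = sigma[np.ix_(o, o)]
            som = sigma[np.ix_(o, m)]
            A = np.linalg.solve(soo, som).T  # conditional regression coefficients
            cond_mean = mu[m] + (Xp[:, o] - mu[o]) @ A.T
            cond_cov = sigma[np.ix_(m, m)] - A @ som
            Xf = Xp.copy()
            Xf[:, m] = cond_mean
            s1 += Xf.sum(axis=0)
            s2 += Xf.T @ Xf
            s2[np.ix_(m, m)] += len(rows) * cond_cov
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new) + ridge * np.eye(k)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < config.em_tol:
            return mu, sigma
    raise ImputationError(
        f"EM did not converge in {config.max_em_iters} iterations (last delta {delta:.3g})"
    )


def _chol_psd(C: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of semi-definite conditional covariances."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((C + C.T) / 2.0)
        return V * np.sqrt(np.clip(w, 0.0, None))


def _draw_completion(X: np.ndarray, missing, groups, mu, sigma, rng) -> np.ndarray:
    filled = np.zeros_like(X)
    for rows, miss in groups:
        if not miss.any():
            continue
        o = ~miss
        m = miss
        soo = sigma[np.ix_(o, o)]
        som = sigma[np.ix_(o, m)]
        A = np.linalg.solve(soo, som).T
        cond_mean = mu[m] + (X[np.ix_(rows, np.nonzero(o)[0])] - mu[o]) @ A.T
        L = _chol_psd(sigma[np.ix_(m, m)] - A @ som)
        noise = rng.standard_normal((len(rows), int(m.sum()))) @ L.T
        filled[np.ix_(rows, np.nonzero(m)[0])] = cond_mean + noise
    return filled


def multiple_impute(X: np.ndarray, config: ImputationConfig | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing cells of ``X``; returns ``(completed, imputed_mask)``.

    Deterministic for a fixed ``(X, config)``: all randomness flows from
    ``config.seed`` through a PCG64 generator.
    """
    config = config or ImputationConfig()
    X = np.asarray(X, dtype=float)
    missing = np.isnan(X)
    if not missing.any():
        return X.copy(), missing
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    groups = list(_patterns(missing))
    acc = np.zeros_like(X)
    for _ in range(config.n_imputations):
        boot = rng.integers(0, n, size=n)
        mu, sigma = em_fit(X[boot], config)
        acc += _draw_completion(X, missing, groups, mu, sigma, rng)
    completed = X.copy()
    completed[missing] = acc[missing] / config.n_imputations
    return completed, missing


def impute_query(query: np.ndarray, reference_pool: np.ndarray,
                 config: ImputationConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Impute a (typically small) query by merging it with a complete reference pool.

    The pool (subsampled to ``config.reference_size`` rows when larger) is
    stacked under the query, the union is imputed, and only the query rows are
    returned, in input order.
    """
    config = config or ImputationConfig()
    query = np.asarray(query, dtype=float)
    pool = np.asarray(reference_pool, dtype=float)
    if pool.ndim != 2 or pool.shape[1] != query.shape[1]:
        raise ValidationError(
            f"reference pool has {pool.shape[1] if pool.ndim == 2 else '?'} systems, "
            f"query has {query.shape[1]}"
        )
    if np.isnan(pool).any():
        raise ValidationError("reference pool must be complete (no missing values)")
    if pool.shape[0] > config.reference_size:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        keep = rng.choice(pool.shape[0], size=config.reference_size, replace=False)
        pool = pool[keep]
    stacked = np.vstack([query, pool])
    completed, mask = multiple_impute(stacked, config)
    nq = query.shape[0]
    return completed[:nq], mask[:nq]
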