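"""Benchmark error models for head-to-head calibration comparisons.

Four alternatives to the multiplicative/additive model:

1. *Variance-based*: the empirical between-replicate variance of fitness
   scores, divided by the number of replicates.
2. *Bayesian-regularized variance*: the empirical variance shrunk towards a
   prior obtained from a regression on input counts and fitness.
3. *Count-based*: pure Poisson counting statistics, ``1/N_in + 1/N_out``.
4. *Random-effects* (Enrich2-style): count-based variances inflated by a
   per-variant random-effects term ``s_i^2 >= 0`` chosen so the merged error
   matches the empirical variance whenever the latter is larger.

All are exposed both as plain functions and as small sklearn-style
estimators sharing the ``fit`` + fitted-attribute convention so they can be
swapped into the leave-one-out diagnostics.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "variance_based_error",
    "bayes_regularized_error",
    "count_based_error",
    "enrich2_random_effects",
    "solve_random_effect",
    "fit_variance_prior",
    "VarianceErrorModel",
    "BayesRegularizedErrorModel",
    "CountErrorModel",
    "Enrich2ErrorModel",
]


def _empirical_variance(fitness: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise variance (ddof=1) over finite entries and the count used."""
    F = np.asarray(fitness, dtype=float)
    ok = np.isfinite(F)
    n = ok.sum(axis=1)
    mean = np.where(n > 0, np.nansum(np.where(ok, F, 0.0), axis=1) / np.maximum(n, 1), np.nan)
    ss = np.nansum(np.where(ok, (F - mean[:, None]) ** 2, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n >= 2, ss / np.maximum(n - 1, 1), np.nan)
    return var, n


def variance_based_error(fitness: np.ndarray) -> np.ndarray:
    """Merged variance ``var(f_i) / n`` from the empirical replicate spread.

    NaN for variants with fewer than two usable replicates.
    """
    var, n = _empirical_variance(fitness)
    return var / n


def fit_variance_prior(
    fitness: np.ndarray,
    input_counts: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Prior variance per variant from a regression on counts and fitness.

    Ordinary least squares of ``log(var(f_i))`` on ``log(min_r N_input)`` and
    the mean fitness score (3 coefficients incl. intercept); the
    exponentiated prediction is the per-variant prior variance.
    """
    var, n = _empirical_variance(fitness)
    F = np.asarray(fitness, dtype=float)
    Nin = np.asarray(input_counts, dtype=float)
    fbar = np.nanmean(F, axis=1)
    min_in = np.nanmin(np.where(Nin > 0, Nin, np.nan), axis=1)
    ok = np.isfinite(var) & (var > 0) & np.isfinite(fbar) & np.isfinite(min_in)
    if ok.sum() < 4:
        raise ValueError("too few variants to fit the variance prior regression")
    X = np.column_stack([np.ones(ok.sum()), np.log(min_in[ok]), fbar[ok]])
    coef, *_ = np.linalg.lstsq(X, np.log(var[ok] + eps), rcond=None)
    Xall = np.column_stack([np.ones(len(var)), np.log(min_in), fbar])
    with np.errstate(invalid="ignore"):
        return np.exp(Xall @ coef)


def bayes_regularized_error(
    fitness: np.ndarray,
    prior_variance: np.ndarray,
    d: float = 3.0,
) -> np.ndarray:
    """Merged variance regularizing the empirical spread with a prior.

    ``sigma_bar^2_i = (d * sigma^2_prior,i + (n-1) * var(f_i)) / ((d+n-2) * n)``
    with ``d`` the degrees of freedom of the prior regression.
    """
    var, n = _empirical_variance(fitness)
    prior = np.asarray(prior_variance, dtype=float)
    denom = (d + n - 2.0) * n
    if np.any((denom <= 0) & (n >= 2)):
        raise ValueError("d + n - 2 must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, (d * prior + (n - 1) * var) / denom, np.nan)


def count_based_error(
    input_counts: np.ndarray, output_counts: np.ndarray
) -> np.ndarray:
    """Poisson variance per replicate, ``1/N_in + 1/N_out``; NaN for zero counts."""
    Nin = np.asarray(input_counts, dtype=float)
    Nout = np.asarray(output_counts, dtype=float)
    ok = (Nin > 0) & (Nout > 0)
    with np.errstate(divide="ignore"):
        return np.where(ok, 1.0 / Nin + 1.0 / Nout, np.nan)


def _harmonic_merge(var: np.ndarray) -> np.ndarray:
    ok = np.isfinite(var) & (var > 0)
    w = np.where(ok, 1.0 / np.where(ok, var, 1.0), 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.where(w > 0, 1.0 / w, np.nan)


def solve_random_effect(
    replicate_variances: np.ndarray,
    target_variance: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Solve ``1 / sum_r (sigma_r^2 + s^2)^-1 = target`` for ``s^2 >= 0``.

    The left side is strictly increasing in ``s^2``, so a plain bisection on
    ``[0, n * target]`` brackets the unique root; returns 0 when the
    harmonic merge of the count variances already reaches the target.
    """
    v = np.asarray(replicate_variances, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 2 or not np.isfinite(target_variance):
        return np.nan

    def merged(s2: float) -> float:
        return 1.0 / np.sum(1.0 / (v + s2))

    if merged(0.0) >= target_variance:
        return 0.0
    lo, hi = 0.0, n * target_variance
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if merged(mid) < target_variance:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol:
            break
    return 0.5 * (lo + hi)


def enrich2_random_effects(
    fitness: np.ndarray,
    input_counts: np.ndarray,
    output_counts: np.ndarray,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant random-effects terms and the resulting merged variances.

    Returns ``(s2, merged_variance)``; ``s2_i = 0`` whenever the empirical
    variance does not exceed the count-based merged variance.
    """
    var, n = _empirical_variance(fitness)
    count_var = count_based_error(input_counts, output_counts)
    F = np.asarray(fitness, dtype=float)
    count_var = np.where(np.isfinite(F), count_var, np.nan)
    s2 = np.full(len(var), np.nan)
    merged = np.full(len(var), np.nan)
    for i in range(len(var)):
        if n[i] < 2 or not np.isfinite(var[i]):
            continue
        v = count_var[i][np.isfinite(count_var[i])]
        if len(v) < 2:
            continue
        s2[i] = solve_random_effect(v, var[i], tol=tol)
        merged[i] = 1.0 / np.sum(1.0 / (v + s2[i]))
    return s2, merged


# -- estimator wrappers ----------------------------------------------------


class CountErrorModel(BaseEstimator):
    """Pure Poisson count-based error model (no free parameters)."""

    def fit(self, fitness, input_counts, output_counts, n_subs=None):
        self.n_replicates_ = np.asarray(fitness).shape[1]
        return self

    def predict_variance(self, input_counts, output_counts):
        return count_based_error(input_counts, output_counts)

    def merged_variance(self, fitness, input_counts, output_counts):
        var = count_based_error(input_counts, output_counts)
        return _harmonic_merge(np.where(np.isfinite(np.asarray(fitness, float)), var, np.nan))


class VarianceErrorModel(BaseEstimator):
    """Empirical between-replicate variance model."""

    def fit(self, fitness, input_counts=None, output_counts=None, n_subs=None):
        fitness = np.asarray(fitness, dtype=float)
        self.merged_variance_ = variance_based_error(fitness)
        _, self.n_used_ = _empirical_variance(fitness)
        self.n_replicates_ = fitness.shape[1]
        return self

    def holdout_variance(self) -> np.ndarray:
        """Test-replicate variance: training merged variance times n/(n-1)."""
        n = self.n_used_
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n >= 2, self.merged_variance_ * n / (n - 1.0), np.nan)


class BayesRegularizedErrorModel(BaseEstimator):
    """Bayesian regularization of the empirical variance towards a fitted prior."""

    def __init__(self, d: float = 3.0):
        self.d = d

    def fit(self, fitness, input_counts, output_counts=None, n_subs=None):
        fitness = np.asarray(fitness, dtype=float)
        self.prior_variance_ = fit_variance_prior(fitness, input_counts)
        self.merged_variance_ = bayes_regularized_error(fitness, self.prior_variance_, self.d)
        _, self.n_used_ = _empirical_variance(fitness)
        self.n_replicates_ = fitness.shape[1]
        return self

    def holdout_variance(self) -> np.ndarray:
        n = self.n_used_
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n >= 2, self.merged_variance_ * n / (n - 1.0), np.nan)


class Enrich2ErrorModel(BaseEstimator):
    """Count-based model with per-variant random-effects inflation."""

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    def fit(self, fitness, input_counts, output_counts, n_subs=None):
        self.s2_, self.merged_variance_ = enrich2_random_effects(
            fitness, input_counts, output_counts, tol=self.tol
        )
        self.n_replicates_ = np.asarray(fitness).shape[1]
        return self

    def holdout_variance(self, input_counts_test, output_counts_test) -> np.ndarray:
        """Count-based test variance plus the training random-effects term."""
        return count_based_error(input_counts_test, output_counts_test) + self.s2_
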