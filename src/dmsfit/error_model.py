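"""Replicate-specific multiplicative/additive error model for DMS fitness scores.

The measurement error variance of a fitness score is modelled as

    sigma^2(f_{r,i}) = m_input_r / N_input_{r,i} + m_output_r / N_output_{r,i} + a_r

with a multiplicative modifier per sample side (bounded below by the Poisson
baseline, ``m >= 1``) and a count-independent additive variance floor per
replicate (``a >= 0``).  The 3n parameters are estimated by weighted least
squares of the empirical between-replicate variance of fitness scores
against the average model prediction, summed over *all* replicate subsets
of size >= 2 — the lower-order subsets are what makes the per-replicate
additive terms identifiable.  Because the model mean is linear in the
parameters, the bounded arg-min is an exact bounded-variable least-squares
problem and is solved as such; the fit is repeated on bootstrap samples of
the high-confidence variant pool and bootstrap-mean parameters are the
operative estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator

from .fitness import FitnessTable
from .io import ExperimentDesign, VariantCountTable, select_high_confidence

__all__ = [
    "FitConfig",
    "ErrorModelParams",
    "DimsumErrorModel",
    "model_variance",
    "enumerate_subsets",
    "compute_fit_weights",
    "objective",
    "fit_error_model",
    "predict_variant_error",
]


@dataclass
class FitConfig:
    """Bootstrap/fitting configuration for the error model."""

    n_bootstraps: int = 100
    max_variants_per_bootstrap: int = 10_000
    random_seed: int | None = None
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_bootstraps < 0:
            raise ValueError("n_bootstraps must be >= 0")
        if self.max_variants_per_bootstrap < 1:
            raise ValueError("max_variants_per_bootstrap must be >= 1")


@dataclass
class ErrorModelParams:
    """Fitted error-model terms with bootstrap summaries.

    ``m_input``, ``m_output`` and ``a`` are bootstrap means (the operative
    estimates); ``bootstrap`` holds the raw per-bootstrap parameter draws
    with shape (n_bootstraps, n_replicates) per term.
    """

    replicate_ids: list[str]
    m_input: np.ndarray
    m_output: np.ndarray
    a: np.ndarray
    bootstrap: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-parameter bootstrap mean, sd and 5th/95th percentiles."""
        rows = []
        for term, mean in (("m_input", self.m_input), ("m_output", self.m_output), ("a", self.a)):
            draws = self.bootstrap.get(term)
            for k, rep in enumerate(self.replicate_ids):
                row = {"term": term, "replicate": rep, "mean": mean[k]}
                if draws is not None and len(draws) > 1:
                    row["sd"] = float(np.std(draws[:, k], ddof=1))
                    row["p5"] = float(np.percentile(draws[:, k], 5))
                    row["p95"] = float(np.percentile(draws[:, k], 95))
                else:
                    row["sd"] = np.nan
                    row["p5"] = np.nan
                    row["p95"] = np.nan
                rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {}
        summ = self.summary().set_index(["replicate", "term"])
        for k, rep in enumerate(self.replicate_ids):
            out[rep] = {
                "m_input": float(self.m_input[k]),
                "m_output": float(self.m_output[k]),
                "a": float(self.a[k]),
                "sqrt_a": float(np.sqrt(self.a[k])),
                "bootstrap_sd": {
                    term: float(summ.loc[(rep, term), "sd"])
                    for term in ("m_input", "m_output", "a")
                },
                "ci90": {
                    term: [float(summ.loc[(rep, term), "p5"]), float(summ.loc[(rep, term), "p95"])]
                    for term in ("m_input", "m_output", "a")
                },
            }
        return out

    def variance(self, input_counts: np.ndarray, output_counts: np.ndarray) -> np.ndarray:
        return model_variance(self.m_input, self.m_output, self.a, input_counts, output_counts)


def model_variance(
    m_input: np.ndarray | float,
    m_output: np.ndarray | float,
    a: np.ndarray | float,
    n_input: np.ndarray,
    n_output: np.ndarray,
) -> np.ndarray:
    """Model variance ``m_in/N_in + m_out/N_out + a``; NaN where a count is <= 0."""
    n_input = np.asarray(n_input, dtype=float)
    n_output = np.asarray(n_output, dtype=float)
    ok = (n_input > 0) & (n_output > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = m_input / n_input + m_output / n_output + a
    return np.where(ok, var, np.nan)


def enumerate_subsets(n_replicates: int) -> list[tuple[int, ...]]:
    """All replicate-index subsets of size >= 2, largest first."""
    if n_replicates < 2:
        raise ValueError("error model needs at least two replicates")
    subsets: list[tuple[int, ...]] = []
    for size in range(n_replicates, 1, -1):
        subsets.extend(combinations(range(n_replicates), size))
    return subsets


def _class_weights(n_subs: np.ndarray) -> np.ndarray:
    """Per-variant mutation-class down-weighting ``1/sqrt(max(n_m, sqrt(n_total)))``.

    Variants sharing a substitution count form a class of size ``n_m``;
    dividing by the class-size term places relatively more weight on the
    typically fewer low-order mutants, which carry most of the information
    about the additive terms.
    """
    n_total = len(n_subs)
    classes, inverse, counts = np.unique(n_subs, return_inverse=True, return_counts=True)
    factor = 1.0 / np.sqrt(np.maximum(counts, np.sqrt(n_total)))
    return factor[inverse]


def compute_fit_weights(
    n_R: int,
    mean_poisson_variance: np.ndarray,
    n_m: np.ndarray | int,
    n_total: int,
) -> np.ndarray:
    """Per-variant fit weight for one replicate subset.

    The weight is the product of (1) the subset size, (2) the inverse
    *squared* subset-averaged Poisson count variance — weighting squared
    deviations by an inverse squared scale turns each summand into a squared
    relative deviation, so relative rather than absolute deviations are
    minimized — and (3) the inverse mutation-class term
    ``1/sqrt(max(n_m, sqrt(n_total)))``.
    """
    mean_poisson_variance = np.asarray(mean_poisson_variance, dtype=float)
    n_m = np.asarray(n_m, dtype=float)
    return n_R / mean_poisson_variance**2 / np.sqrt(np.maximum(n_m, np.sqrt(n_total)))


def _design_matrix(
    F: np.ndarray,
    inv_in: np.ndarray,
    inv_out: np.ndarray,
    n_subs: np.ndarray,
    subsets: Sequence[tuple[int, ...]],
    rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack the weighted least-squares system over all replicate subsets.

    Returns (X, y, w): one row per (subset, variant) pair; columns are the
    3n parameters ordered [m_input..., m_output..., a...].
    """
    n_rep = F.shape[1]
    cw = _class_weights(n_subs[rows])
    X_blocks, y_blocks, w_blocks = [], [], []
    for R in subsets:
        k = len(R)
        cols = list(R)
        Fr = F[np.ix_(rows, cols)]
        y = Fr.var(axis=1, ddof=1)
        pin = inv_in[np.ix_(rows, cols)]
        pout = inv_out[np.ix_(rows, cols)]
        pois = (pin + pout).mean(axis=1)
        w = (k / pois**2) * cw
        Xb = np.zeros((len(rows), 3 * n_rep))
        Xb[:, cols] = pin / k
        Xb[:, [n_rep + c for c in cols]] = pout / k
        Xb[:, [2 * n_rep + c for c in cols]] = 1.0 / k
        X_blocks.append(Xb)
        y_blocks.append(y)
        w_blocks.append(w)
    return np.vstack(X_blocks), np.concatenate(y_blocks), np.concatenate(w_blocks)


def _solve_bounded(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_rep: int, tol: float) -> np.ndarray:
    # Vanishing ridge toward the Poisson null (m=1, a=0), scaled per column
    # to ~1e-10 of that parameter's own curvature.  Identifiable parameters
    # are unaffected, but the minimizer becomes unique on degenerate
    # directions — notably the additive terms with only two replicates,
    # which are then split equally between the replicates.
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    col_curv = (Xw**2).sum(axis=0)
    lam = np.sqrt(1e-10 * np.where(col_curv > 0, col_curv, col_curv.max()))
    null = np.concatenate([np.ones(2 * n_rep), np.zeros(n_rep)])
    Xa = np.vstack([Xw, np.diag(lam)])
    ya = np.concatenate([y * sw, lam * null])
    lb = np.concatenate([np.ones(2 * n_rep), np.zeros(n_rep)])
    ub = np.full(3 * n_rep, np.inf)
    res = lsq_linear(Xa, ya, bounds=(lb, ub), method="bvls", tol=tol)
    if not res.success:  # pragma: no cover - bvls is exact on these sizes
        res = lsq_linear(Xa, ya, bounds=(lb, ub), method="trf", tol=tol)
        if not res.success:
            raise RuntimeError(f"bounded least squares failed: {res.message}")
    return res.x


def objective(
    m_input: np.ndarray,
    m_output: np.ndarray,
    a: np.ndarray,
    fitness: np.ndarray,
    input_counts: np.ndarray,
    output_counts: np.ndarray,
    n_subs: np.ndarray | None = None,
    subsets: Sequence[tuple[int, ...]] | None = None,
) -> float:
    """Weighted sum of squared deviations between empirical and model variance.

    Sums, over every replicate subset R of size >= 2 and every variant,
    ``w_{R,i} * (var(f_{R,i}) - mean_{r in R} sigma^2(f_{r,i}))^2`` where the
    empirical variance uses denominator ``n_R - 1``.
    """
    F = np.asarray(fitness, dtype=float)
    inv_in = 1.0 / np.asarray(input_counts, dtype=float)
    inv_out = 1.0 / np.asarray(output_counts, dtype=float)
    m_input = np.asarray(m_input, dtype=float)
    m_output = np.asarray(m_output, dtype=float)
    a = np.asarray(a, dtype=float)
    if n_subs is None:
        n_subs = np.zeros(len(F), dtype=int)
    if subsets is None:
        subsets = enumerate_subsets(F.shape[1])
    cw = _class_weights(np.asarray(n_subs))
    total = 0.0
    for R in subsets:
        cols = list(R)
        k = len(R)
        emp = F[:, cols].var(axis=1, ddof=1)
        model = (
            m_input[cols] * inv_in[:, cols]
            + m_output[cols] * inv_out[:, cols]
            + a[cols]
        ).mean(axis=1)
        pois = (inv_in[:, cols] + inv_out[:, cols]).mean(axis=1)
        w = (k / pois**2) * cw
        total += float((w * (emp - model) ** 2).sum())
    return total


class DimsumErrorModel(BaseEstimator):
    """Sklearn-style estimator for the multiplicative/additive error model.

    Parameters
    ----------
    n_bootstraps : int
        Number of bootstrap refits; the reported parameters are bootstrap
        means.  ``0`` performs a single fit on the full pool (no bootstrap
        summaries).
    max_variants_per_bootstrap : int
        Cap on the number of variants drawn (with replacement) per bootstrap.
    random_state : int or None
        Seed for the bootstrap resampling.
    tol : float
        Optimality tolerance of the bounded least-squares solver.

    Attributes (after :meth:`fit`)
    ------------------------------
    m_input_, m_output_, a_ : ndarray of shape (n_replicates,)
        Fitted terms, bounds ``m >= 1``, ``a >= 0``.
    bootstrap_estimates_ : ndarray of shape (n_bootstraps, 3*n_replicates) or None
    n_replicates_, n_variants_ : int
    """

    def __init__(
        self,
        n_bootstraps: int = 100,
        max_variants_per_bootstrap: int = 10_000,
        random_state: int | None = None,
        tol: float = 1e-12,
    ) -> None:
        self.n_bootstraps = n_bootstraps
        self.max_variants_per_bootstrap = max_variants_per_bootstrap
        self.random_state = random_state
        self.tol = tol

    def fit(
        self,
        fitness: np.ndarray,
        input_counts: np.ndarray,
        output_counts: np.ndarray,
        n_subs: np.ndarray | None = None,
    ) -> "DimsumErrorModel":
        """Fit on a high-confidence pool of variants.

        ``fitness``, ``input_counts`` and ``output_counts`` are
        (n_variants, n_replicates) arrays; rows with non-finite fitness or
        non-positive counts anywhere are dropped from the pool.
        """
        F = np.atleast_2d(np.asarray(fitness, dtype=float))
        Nin = np.atleast_2d(np.asarray(input_counts, dtype=float))
        Nout = np.atleast_2d(np.asarray(output_counts, dtype=float))
        if not (F.shape == Nin.shape == Nout.shape):
            raise ValueError("fitness and count arrays must share one shape")
        n_rep = F.shape[1]
        if n_rep < 2:
            raise ValueError("error model needs at least two replicates")
        ok = np.isfinite(F).all(axis=1) & (Nin > 0).all(axis=1) & (Nout > 0).all(axis=1)
        F, Nin, Nout = F[ok], Nin[ok], Nout[ok]
        ns = np.zeros(len(F), dtype=int) if n_subs is None else np.asarray(n_subs)[ok]
        pool = len(F)
        if pool < 2:
            raise ValueError("fewer than two usable variants in the fitting pool")
        inv_in, inv_out = 1.0 / Nin, 1.0 / Nout
        subsets = enumerate_subsets(n_rep)
        rng = np.random.default_rng(self.random_state)
        n_fits = max(self.n_bootstraps, 1)
        draw_size = min(self.max_variants_per_bootstrap, pool)
        est = np.empty((n_fits, 3 * n_rep))
        for b in range(n_fits):
            if self.n_bootstraps > 0:
                rows = rng.integers(0, pool, size=draw_size)
            else:
                rows = np.arange(pool)
            X, y, w = _design_matrix(F, inv_in, inv_out, ns, subsets, rows)
            est[b] = _solve_bounded(X, y, w, n_rep, self.tol)
        mean = est.mean(axis=0)
        self.n_replicates_ = n_rep
        self.n_variants_ = pool
        self.m_input_ = mean[:n_rep]
        self.m_output_ = mean[n_rep : 2 * n_rep]
        self.a_ = mean[2 * n_rep :]
        self.bootstrap_estimates_ = est if self.n_bootstraps > 0 else None
        return self

    def predict_variance(
        self, input_counts: np.ndarray, output_counts: np.ndarray
    ) -> np.ndarray:
        """Model variance for every variant/replicate given reported counts."""
        if not hasattr(self, "m_input_"):
            raise RuntimeError("model is not fitted")
        return model_variance(self.m_input_, self.m_output_, self.a_, input_counts, output_counts)

    def to_params(self, replicate_ids: Sequence[str] | None = None) -> ErrorModelParams:
        if not hasattr(self, "m_input_"):
            raise RuntimeError("model is not fitted")
        ids = list(replicate_ids) if replicate_ids is not None else [
            str(k + 1) for k in range(self.n_replicates_)
        ]
        n = self.n_replicates_
        boot = {}
        if self.bootstrap_estimates_ is not None:
            est = self.bootstrap_estimates_
            boot = {
                "m_input": est[:, :n],
                "m_output": est[:, n : 2 * n],
                "a": est[:, 2 * n :],
            }
        return ErrorModelParams(ids, self.m_input_, self.m_output_, self.a_, boot)


def fit_error_model(
    ft: FitnessTable,
    counts: VariantCountTable,
    design: ExperimentDesign,
    config: FitConfig | None = None,
    hc_mask: np.ndarray | None = None,
) -> ErrorModelParams:
    """Fit the error model on the high-confidence pool of a dataset.

    Thin wrapper around :class:`DimsumErrorModel`: selects the
    high-confidence variants (unless ``hc_mask`` is given), excludes the
    wild-type row (its scores are the normalization reference and carry no
    independent error information), fits with bootstrap, and returns
    :class:`ErrorModelParams` keyed by replicate id.
    """
    config = config or FitConfig()
    if hc_mask is None:
        hc_mask = select_high_confidence(counts, design).mask
    pool = np.asarray(hc_mask, dtype=bool) & ~counts.is_wildtype
    F = ft.fitness.to_numpy(dtype=float)[pool]
    Nin = counts.input_counts(design)[pool]
    Nout = counts.output_counts(design)[pool]
    ns = counts.n_subs[pool]
    model = DimsumErrorModel(
        n_bootstraps=config.n_bootstraps,
        max_variants_per_bootstrap=config.max_variants_per_bootstrap,
        random_state=config.random_seed,
        tol=config.tol,
    ).fit(F, Nin, Nout, n_subs=ns)
    return model.to_params(design.replicate_ids)


def predict_variant_error(
    params: ErrorModelParams,
    counts: VariantCountTable,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Model variance for every variant and replicate of a count table."""
    var = params.variance(counts.input_counts(design), counts.output_counts(design))
    return pd.DataFrame(var, index=counts.variant_ids, columns=design.replicate_ids)
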